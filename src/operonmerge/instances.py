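"""Training-instance construction, merge-candidate discovery, featurization.

An instance (training example or merge candidate) is summarized by four
statistics of its pairwise ABLIM distances: minimum, mean, sample standard
deviation and maximum.  Training instances use every within-instance gene
pair; merge candidates use only cross-prior pairs — distances internal to a
prior are excluded from candidate features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from operonmerge._errors import ValidationError
from operonmerge.expression import DielCall, ExpressionProfile, ablim_distance
from operonmerge.io_formats import GeneCatalog, OperonPrediction

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("d_min", "d_mean", "d_sd", "d_max")


@dataclass(frozen=True)
class FeatureVector:
    """(min, mean, sample sd, max) of an instance's ABLIM distances."""

    d_min: float
    d_mean: float
    d_sd: float
    d_max: float

    def __post_init__(self) -> None:
        vals = (self.d_min, self.d_mean, self.d_sd, self.d_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite feature vector {vals}")
        if not (self.d_min <= self.d_mean <= self.d_max and self.d_sd >= 0):
            raise ValidationError(f"inconsistent feature vector {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d_min, self.d_mean, self.d_sd, self.d_max])


@dataclass(frozen=True)
class TrainingInstance:
    instance_id: str
    gene_ids: tuple[str, ...]
    label: str  # "positive" or "negative"
    features: FeatureVector


@dataclass(frozen=True)
class MergeCandidate:
    """An adjacent pair of priors, optionally featurized, scored and decided."""

    prior1: OperonPrediction
    prior2: OperonPrediction
    cross_pairs: tuple[tuple[str, str], ...]
    features: FeatureVector | None = None
    score: float | None = None
    merged: bool | None = None

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.prior1.gene_ids + self.prior2.gene_ids


def featurize(pair_distances: Sequence[float]) -> FeatureVector:
    """Summarize pairwise distances as (min, mean, sample sd, max).

    The standard deviation uses the n-1 denominator and is 0 for a single
    distance.  Permutation-invariant by construction.
    """
    if len(pair_distances) == 0:
        raise ValidationError("featurize requires at least one distance")
    # Sorting makes the statistics exactly permutation-invariant (summation
    # order matters at the ulp level).
    arr = np.sort(np.asarray(pair_distances, dtype=float))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    lo, hi = float(np.min(arr)), float(np.max(arr))
    # np.mean can land 1 ulp outside [min, max]; clamp to keep the invariant.
    mean = min(max(float(np.mean(arr)), lo), hi)
    return FeatureVector(d_min=lo, d_mean=mean, d_sd=sd, d_max=hi)


def _all_pair_distances(
    gene_ids: Sequence[str], profiles: Mapping[str, ExpressionProfile]
) -> list[float]:
    return [
        ablim_distance(profiles[a], profiles[b])
        for i, a in enumerate(gene_ids)
        for b in gene_ids[i + 1 :]
    ]


def _has_diel(gene_ids: Sequence[str], diel: Mapping[str, DielCall]) -> bool:
    return any(g in diel and diel[g].is_diel for g in gene_ids)


def build_positive_instances(
    priors: Sequence[OperonPrediction],
    profiles: Mapping[str, ExpressionProfile],
    diel: Mapping[str, DielCall],
) -> list[TrainingInstance]:
    """One positive instance per prior with >= 2 usable profiles and a diel gene.

    Features come from all within-instance gene pairs (over usable genes).
    Skipped priors are logged with the failing rule.
    """
    out = []
    skipped = {"single_gene": 0, "missing_profile": 0, "no_diel_gene": 0}
    for prior in priors:
        usable = [g for g in prior.gene_ids if g in profiles]
        if len(prior.gene_ids) < 2:
            skipped["single_gene"] += 1
            continue
        if len(usable) < 2:
            skipped["missing_profile"] += 1
            continue
        if not _has_diel(prior.gene_ids, diel):
            skipped["no_diel_gene"] += 1
            continue
        out.append(
            TrainingInstance(
                instance_id=f"pos_{prior.operon_id}",
                gene_ids=tuple(usable),
                label="positive",
                features=featurize(_all_pair_distances(usable, profiles)),
            )
        )
    logger.info(
        "positive instances: %d built, skipped %s from %d priors",
        len(out),
        skipped,
        len(priors),
    )
    return out


def _parse_size_policy(size_policy: str) -> tuple[str, int | None]:
    if size_policy == "match_positive_distribution":
        return "match", None
    if size_policy.startswith("fixed:"):
        k = int(size_policy.split(":", 1)[1])
        if k < 2:
            raise ValidationError(f"fixed window size must be >= 2, got {k}")
        return "fixed", k
    raise ValidationError(f"unknown size_policy {size_policy!r}")


def build_negative_instances(
    catalog: GeneCatalog,
    profiles: Mapping[str, ExpressionProfile],
    diel: Mapping[str, DielCall],
    size_policy: str = "match_positive_distribution",
    seed: int | None = None,
    positive_sizes: Sequence[int] | None = None,
    allow_overlap: bool = False,
) -> list[TrainingInstance]:
    """Negative instances: consecutive-rank windows mixing both strands.

    A window qualifies if it lies in one contig, contains at least one gene
    on each strand, at least one diel gene, and all genes have usable
    profiles.  ``size_policy`` is ``"fixed:k"`` or
    ``"match_positive_distribution"`` (draws sizes from ``positive_sizes``).
    Windows are scanned greedily left to right and are non-overlapping unless
    ``allow_overlap``.
    """
    mode, fixed_k = _parse_size_policy(size_policy)
    if mode == "match":
        if not positive_sizes:
            raise ValidationError(
                "match_positive_distribution requires positive_sizes"
            )
        if seed is None:
            raise ValidationError("stochastic size policy requires a seed")
        rng = np.random.default_rng(seed)
        sizes = np.asarray(sorted(positive_sizes))
    out = []
    for contig in catalog.contigs:
        genes = catalog.genes_in_contig(contig)
        i = 0
        while i < len(genes):
            k = fixed_k if mode == "fixed" else int(rng.choice(sizes))
            window = genes[i : i + k]
            if len(window) < k:
                break
            strands = {catalog.gene(g).strand for g in window}
            ok = (
                strands == {"+", "-"}
                and _has_diel(window, diel)
                and all(g in profiles for g in window)
            )
            if ok:
                out.append(
                    TrainingInstance(
                        instance_id=f"neg_{contig}_{catalog.rank(window[0])}",
                        gene_ids=tuple(window),
                        label="negative",
                        features=featurize(_all_pair_distances(window, profiles)),
                    )
                )
                i += 1 if allow_overlap else k
            else:
                i += 1
    logger.info("negative instances: %d built (policy=%s)", len(out), size_policy)
    return out


def find_merge_candidates(
    priors: Sequence[OperonPrediction],
    catalog: GeneCatalog,
    diel: Mapping[str, DielCall],
) -> list[MergeCandidate]:
    """Adjacent prior pairs eligible for merging.

    Rules: no intervening genes (last rank of prior1 + 1 == first rank of
    prior2), one contig, one strand across both priors, and at least one
    diel gene in EACH prior.  Output is sorted by (contig, rank) and
    deterministic.  Cross pairs are the full prior1 x prior2 product.
    """
    for prior in priors:
        prior.validate(catalog)
    annotated = []
    for prior in priors:
        contig = catalog.gene(prior.gene_ids[0]).contig
        ranks = [catalog.rank(g) for g in prior.gene_ids]
        annotated.append((contig, min(ranks), max(ranks), prior))
    annotated.sort(key=lambda item: (item[0], item[1]))
    out = []
    excluded = {"gap": 0, "strand": 0, "no_diel": 0}
    for (c1, _lo1, hi1, p1), (c2, lo2, _hi2, p2) in zip(annotated, annotated[1:]):
        if c1 != c2:
            continue
        if hi1 + 1 != lo2:
            excluded["gap"] += 1
            continue
        strands = {catalog.gene(g).strand for g in p1.gene_ids + p2.gene_ids}
        if len(strands) > 1:
            excluded["strand"] += 1
            continue
        if not (_has_diel(p1.gene_ids, diel) and _has_diel(p2.gene_ids, diel)):
            excluded["no_diel"] += 1
            continue
        cross = tuple((a, b) for a in p1.gene_ids for b in p2.gene_ids)
        out.append(MergeCandidate(prior1=p1, prior2=p2, cross_pairs=cross))
    logger.info(
        "merge candidates: %d found, excluded %s from %d adjacent pairs",
        len(out),
        excluded,
        len(annotated) - 1,
    )
    return out


def featurize_candidates(
    candidates: Sequence[MergeCandidate],
    profiles: Mapping[str, ExpressionProfile],
) -> list[MergeCandidate]:
    """Attach features from cross-prior pairs only.

    Candidates touching a gene without a usable profile are dropped with a
    logged warning.
    """
    out = []
    dropped = 0
    for cand in candidates:
        if not all(g in profiles for g in cand.gene_ids):
            dropped += 1
            logger.warning(
                "dropping candidate (%s, %s): gene without usable profile",
                cand.prior1.operon_id,
                cand.prior2.operon_id,
            )
            continue
        distances = [
            ablim_distance(profiles[a], profiles[b]) for a, b in cand.cross_pairs
        ]
        out.append(replace(cand, features=featurize(distances)))
    if dropped:
        logger.info("dropped %d candidates lacking profiles", dropped)
    return out


def write_feature_table(
    instances: Sequence[TrainingInstance], path, header_lines: Sequence[str] = ()
) -> None:
    """Interchange TSV: instance_id, label, d_min, d_mean, d_sd, d_max."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("instance_id\tlabel\t" + "\t".join(FEATURE_NAMES) + "\n")
        for inst in instances:
            feats = "\t".join(repr(v) for v in inst.features.as_array())
            fh.write(f"{inst.instance_id}\t{inst.label}\t{feats}\n")
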