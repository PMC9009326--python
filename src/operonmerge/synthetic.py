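"""Synthetic diel genomes, transcriptomes, and deliberately split priors.

The generator lays out transcription units (operons and singleton genes)
along contigs, gives each diel unit a sinusoidal log2-expression signature
with a unit-level phase and gene-level phase jitter, and then emits prior
predictions in which some true operons have been cut in two — with ground
truth recording which adjacent prior pairs should and should not merge.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from operonmerge._errors import ValidationError
from operonmerge.io_formats import (
    ExpressionMatrix,
    GeneCatalog,
    GeneRecord,
    OperonPrediction,
    write_annotation_tsv,
    write_expression_table,
    write_prior_operons,
)

_GENE_LENGTH_BP = 900
_GENE_GAP_BP = 100
_PERIOD_H = 24.0


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    n_contigs: int = 1
    operon_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2}
    )
    p_operon_gene: float = 0.7  # probability a transcription unit is multi-gene
    diel_fraction: float = 0.8
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    amplitude_log2: float = 1.0
    phase_jitter_h: float = 0.0
    noise_sd_log2: float = 0.0
    p_split_prior: float = 0.5
    strand_switch_rate: float = 0.5
    seed: int = 0
    # When set, diel units take phases cyclically from this list (by unit
    # index), guaranteeing adjacent units differ in phase; otherwise phases
    # are drawn Uniform[0, 24).
    phase_choices: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        probs = list(self.operon_size_distribution.values())
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("operon_size_distribution must sum to 1 in [0,1]")
        if any(size < 2 for size in self.operon_size_distribution):
            raise ValidationError("operon sizes must be >= 2 (singletons via p_operon_gene)")
        for name in ("p_operon_gene", "diel_fraction", "p_split_prior", "strand_switch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValidationError("timepoints_h must be strictly increasing, length >= 2")
        if self.n_genes < 1 or self.n_contigs < 1:
            raise ValidationError("n_genes and n_contigs must be positive")


@dataclass
class GroundTruth:
    true_operons: list[OperonPrediction]
    split_pairs: list[tuple[str, str]]
    non_merge_pairs: list[tuple[str, str]]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_genome(config: SimulationConfig) -> tuple[GeneCatalog, list[OperonPrediction]]:
    """Lay out transcription units per contig; returns catalog + true operons.

    ``true_operons`` includes singleton units so that priors derived from
    them keep the catalog fully covered.
    """
    sizes = sorted(config.operon_size_distribution)
    probs = [config.operon_size_distribution[s] for s in sizes]
    per_contig = config.n_genes // config.n_contigs
    if per_contig < 1:
        raise ValidationError("fewer genes than contigs")
    if min(sizes) > per_contig and config.p_operon_gene > 0:
        raise ValidationError(
            f"smallest operon size {min(sizes)} exceeds genes per contig {per_contig}"
        )
    rng = _rng(config, 0)
    records: list[GeneRecord] = []
    units: list[OperonPrediction] = []
    gene_counter = 0
    remaining_total = config.n_genes
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"
        n_here = per_contig if ci < config.n_contigs - 1 else remaining_total
        remaining_total -= n_here
        strand = "+" if rng.random() < 0.5 else "-"
        pos = 0
        left = n_here
        while left > 0:
            if left >= min(sizes) and rng.random() < config.p_operon_gene:
                size = min(int(rng.choice(sizes, p=probs)), left)
            else:
                size = 1
            gene_ids = []
            for _ in range(size):
                gid = f"g{gene_counter + 1:05d}"
                gene_counter += 1
                records.append(
                    GeneRecord(gid, contig, strand, pos, pos + _GENE_LENGTH_BP)
                )
                pos += _GENE_LENGTH_BP + _GENE_GAP_BP
                gene_ids.append(gid)
            units.append(OperonPrediction(f"T{len(units) + 1:04d}", tuple(gene_ids)))
            left -= size
            if rng.random() < config.strand_switch_rate:
                strand = "+" if strand == "-" else "-"
    return GeneCatalog(records), units


def generate_expression(
    catalog: GeneCatalog,
    true_operons: Sequence[OperonPrediction],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Sinusoidal diel units plus Gaussian noise; arrhythmic units are noise.

    Each diel unit gets one base phase; member genes add independent phase
    jitter.  Values are log2-scale and NOT pre-centered (the pipeline
    centers them, as it would real data).
    """
    rng = _rng(config, 1)
    t = np.asarray(config.timepoints_h, dtype=float)
    profiles: dict[str, np.ndarray] = {}
    for ui, unit in enumerate(true_operons):
        unit_is_diel = rng.random() < config.diel_fraction
        if config.phase_choices is not None:
            phase = float(config.phase_choices[ui % len(config.phase_choices)])
        else:
            phase = float(rng.uniform(0.0, _PERIOD_H))
        for gid in unit.gene_ids:
            noise = rng.normal(0.0, config.noise_sd_log2, size=t.size) if (
                config.noise_sd_log2 > 0
            ) else np.zeros(t.size)
            if unit_is_diel:
                jitter = (
                    rng.normal(0.0, config.phase_jitter_h)
                    if config.phase_jitter_h > 0
                    else 0.0
                )
                signal = config.amplitude_log2 * np.sin(
                    2.0 * math.pi * (t - phase - jitter) / _PERIOD_H
                )
            else:
                signal = np.zeros(t.size)
            profiles[gid] = signal + noise
    return ExpressionMatrix(timepoints_h=t, profiles=profiles)


def generate_split_priors(
    true_operons: Sequence[OperonPrediction],
    config: SimulationConfig,
    catalog: GeneCatalog | None = None,
) -> tuple[list[OperonPrediction], GroundTruth]:
    """Cut some true operons in two; record merge / non-merge ground truth.

    Each true operon of size >= 2 is split with probability ``p_split_prior``
    at a uniformly chosen internal boundary.  ``split_pairs`` are prior-id
    pairs whose union is one true operon (should merge); ``non_merge_pairs``
    are adjacent-prior pairs spanning two distinct same-strand, same-contig
    true operons (should not merge).
    """
    rng = _rng(config, 2)
    priors: list[OperonPrediction] = []
    split_pairs: list[tuple[str, str]] = []
    unit_first_prior: dict[str, str] = {}
    unit_last_prior: dict[str, str] = {}

    def _new_prior(gene_ids: tuple[str, ...]) -> OperonPrediction:
        prior = OperonPrediction(f"P{len(priors) + 1:04d}", gene_ids)
        priors.append(prior)
        return prior

    for unit in true_operons:
        size = len(unit.gene_ids)
        if size >= 2 and rng.random() < config.p_split_prior:
            cut = int(rng.integers(1, size))
            first = _new_prior(unit.gene_ids[:cut])
            second = _new_prior(unit.gene_ids[cut:])
            split_pairs.append((first.operon_id, second.operon_id))
            unit_first_prior[unit.operon_id] = first.operon_id
            unit_last_prior[unit.operon_id] = second.operon_id
        else:
            prior = _new_prior(unit.gene_ids)
            unit_first_prior[unit.operon_id] = prior.operon_id
            unit_last_prior[unit.operon_id] = prior.operon_id

    non_merge: list[tuple[str, str]] = []
    if catalog is not None:
        for u1, u2 in zip(true_operons, true_operons[1:]):
            r1 = catalog.gene(u1.gene_ids[-1])
            r2 = catalog.gene(u2.gene_ids[0])
            if r1.contig == r2.contig and r1.strand == r2.strand:
                non_merge.append(
                    (unit_last_prior[u1.operon_id], unit_first_prior[u2.operon_id])
                )
    truth = GroundTruth(
        true_operons=list(true_operons),
        split_pairs=split_pairs,
        non_merge_pairs=non_merge,
    )
    return priors, truth


def generate_dataset(
    config: SimulationConfig,
) -> tuple[GeneCatalog, ExpressionMatrix, list[OperonPrediction], GroundTruth]:
    """Genome + expression + split priors in one deterministic call."""
    catalog, units = generate_genome(config)
    matrix = generate_expression(catalog, units, config)
    priors, truth = generate_split_priors(units, config, catalog=catalog)
    return catalog, matrix, priors, truth


def write_fixture(
    out_dir: str | Path,
    catalog: GeneCatalog,
    matrix: ExpressionMatrix,
    priors: Sequence[OperonPrediction],
    truth: GroundTruth,
    header_lines: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the standard fixture set consumed by the CLI and tests.

    Prior ids are positional in priors.tsv, matching what
    :func:`operonmerge.io_formats.read_prior_operons` will assign on read.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out_dir / "annotation.tsv",
        "expression": out_dir / "expression.tsv",
        "priors": out_dir / "priors.tsv",
        "truth_operons": out_dir / "truth_operons.tsv",
        "truth_splits": out_dir / "truth_splits.tsv",
        "truth_nonmerge": out_dir / "truth_nonmerge.tsv",
    }
    write_annotation_tsv(catalog, paths["annotation"], header_lines)
    write_expression_table(matrix, paths["expression"], header_lines)
    write_prior_operons(priors, paths["priors"], header_lines)
    write_prior_operons(truth.true_operons, paths["truth_operons"], header_lines)
    _write_pairs(truth.split_pairs, paths["truth_splits"], header_lines)
    _write_pairs(truth.non_merge_pairs, paths["truth_nonmerge"], header_lines)
    return paths


def _write_pairs(
    pairs: Sequence[tuple[str, str]], path: Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("prior1_id\tprior2_id\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("prior1_id"):
                continue
            a, b = line.split("\t")
            pairs.append((a, b))
    return pairs
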