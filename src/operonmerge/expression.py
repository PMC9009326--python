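"""Profile normalization, diel-variation calls, and the ABLIM curve distance.

ABLIM (area between linear interpolations of measurements) is the integral
of the absolute difference between the piecewise-linear interpolants of two
expression series sampled at shared timepoints.  Each segment is integrated
exactly: a trapezoid when the difference keeps one sign, two triangles when
it crosses zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from operonmerge._errors import ValidationError
from operonmerge.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's log2-expression series over timepoints in hours."""

    gene_id: str
    timepoints_h: np.ndarray
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValidationError(
                f"profile {self.gene_id!r}: timepoints and values must be "
                f"1-D vectors of equal length"
            )
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"profile {self.gene_id!r}: timepoints must be strictly increasing"
            )
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class DielCall:
    """Range-based diel classification of a profile (log2 units)."""

    gene_id: str
    range_log2: float
    is_diel: bool


def mean_center(profile: ExpressionProfile) -> ExpressionProfile:
    """Subtract the arithmetic mean so the profile averages to zero."""
    if profile.values.size == 0:
        raise ValidationError(f"profile {profile.gene_id!r} is empty")
    return replace(
        profile, values=profile.values - float(np.mean(profile.values)), centered=True
    )


def is_diel(profile: ExpressionProfile, min_fold: float = 2.0) -> DielCall:
    """Call a profile diel if its log2 range reaches log2(min_fold).

    Invariant to mean-centering (the range is translation-invariant).
    """
    if min_fold <= 1:
        raise ValidationError(f"min_fold must be > 1, got {min_fold}")
    if profile.values.size < 2:
        raise ValidationError(
            f"profile {profile.gene_id!r}: diel call needs >= 2 timepoints"
        )
    if not np.all(np.isfinite(profile.values)):
        raise ValidationError(
            f"profile {profile.gene_id!r}: diel call on non-finite values"
        )
    span = float(profile.timepoints_h[-1] - profile.timepoints_h[0])
    if span < 20 or span > 28:
        logger.warning(
            "profile %s spans %.1f h; the diel range assumes roughly one 24-h cycle",
            profile.gene_id,
            span,
        )
    rng = float(np.max(profile.values) - np.min(profile.values))
    return DielCall(profile.gene_id, rng, rng >= math.log2(min_fold))


def ablim_distance(
    a: ExpressionProfile, b: ExpressionProfile, normalize_by_span: bool = True
) -> float:
    """Exact area between the linear interpolants of two profiles.

    Per segment with endpoint differences d0, d1 and width dt:
    same sign -> trapezoid dt*(|d0|+|d1|)/2; opposite signs -> two triangles
    dt*(d0^2+d1^2)/(2*(|d0|+|d1|)).  If ``normalize_by_span``, the total is
    divided by the time span so units are area per hour.
    """
    if a.timepoints_h.size < 2:
        raise ValidationError("ABLIM needs at least 2 timepoints")
    if a.timepoints_h.size != b.timepoints_h.size or not np.allclose(
        a.timepoints_h, b.timepoints_h
    ):
        raise ValidationError(
            f"profiles {a.gene_id!r} and {b.gene_id!r} have mismatched timepoints"
        )
    if not (np.all(np.isfinite(a.values)) and np.all(np.isfinite(b.values))):
        raise ValidationError(
            f"profiles {a.gene_id!r}/{b.gene_id!r}: ABLIM on non-finite values"
        )
    d = a.values - b.values
    dt = np.diff(a.timepoints_h)
    d0, d1 = d[:-1], d[1:]
    abs_sum = np.abs(d0) + np.abs(d1)
    crossing = (d0 * d1) < 0
    areas = np.where(
        crossing,
        dt * (d0 * d0 + d1 * d1) / np.where(abs_sum > 0, 2.0 * abs_sum, 1.0),
        dt * abs_sum / 2.0,
    )
    total = float(np.sum(areas))
    if normalize_by_span:
        total /= float(a.timepoints_h[-1] - a.timepoints_h[0])
    return total


def pairwise_distances(
    profiles: Sequence[ExpressionProfile], normalize_by_span: bool = True
) -> np.ndarray:
    """Symmetric matrix of ABLIM distances with a zero diagonal."""
    if len(profiles) < 2:
        raise ValidationError("pairwise_distances needs at least 2 profiles")
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = ablim_distance(
                    profiles[i], profiles[j], normalize_by_span=normalize_by_span
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"pair ({profiles[i].gene_id}, {profiles[j].gene_id}): {exc}"
                ) from exc
    return out


def profiles_from_matrix(
    matrix: ExpressionMatrix, center: bool = True
) -> dict[str, ExpressionProfile]:
    """Extract usable profiles from a matrix, mean-centering by default.

    Profiles with missing values (or fewer than 2 timepoints) are excluded
    with a logged warning; downstream featurization must not touch them.
    """
    out: dict[str, ExpressionProfile] = {}
    dropped = 0
    for gid in matrix.profiles:
        if not matrix.is_usable(gid):
            dropped += 1
            continue
        profile = ExpressionProfile(gid, matrix.timepoints_h, matrix.profiles[gid])
        out[gid] = mean_center(profile) if center else profile
    if dropped:
        logger.warning("excluded %d profiles with missing values or length < 2", dropped)
    return out


def diel_calls(
    profiles: Mapping[str, ExpressionProfile], min_fold: float = 2.0
) -> dict[str, DielCall]:
    """Diel calls for every profile in the mapping."""
    return {gid: is_diel(p, min_fold=min_fold) for gid, p in profiles.items()}
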