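"""Chance estimation, top-percent summaries, and group-level inference.

Chance for analyses without an a-priori baseline is estimated
non-parametrically by circularly misaligning the model features against the
brain data (the rolling null) and recomputing the same top-percent summary
at every shift; chance is the mean of that null distribution. Group
significance of the functional-over-anatomical percent improvement comes
from a subject-level bootstrap: the effect is significant iff the lower
bound of the 95% CI is above 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .engine import MetricMap, run_rsa_searchlight, run_searchlight
from .kernels import FeatureSeries
from .neighborhoods import FunctionalCoordinates, NeighborhoodMap

logger = logging.getLogger(__name__)

__all__ = [
    "NullSummary",
    "ImprovementSummary",
    "top_percent_summary",
    "rolling_null_chance",
    "percent_improvement",
    "bootstrap_improvement",
    "contribution_map",
    "median_anatomical_distance",
    "compare_functional_spaces",
]


@dataclass(frozen=True)
class NullSummary:
    """Rolling-null statistics: one summary value per nonzero shift."""

    null_values: np.ndarray
    shifts: np.ndarray
    chance: float

    @classmethod
    def from_values(cls, values: Sequence[float], shifts: Sequence[int]) -> "NullSummary":
        vals = np.asarray(values, dtype=np.float64)
        return cls(null_values=vals, shifts=np.asarray(shifts, dtype=np.intp), chance=float(vals.mean()))


@dataclass(frozen=True)
class ImprovementSummary:
    """Group percent-improvement with bootstrap CI and tail probability."""

    per_subject_improvement: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int

    @property
    def significant(self) -> bool:
        return self.ci_low > 0


def top_percent_summary(metric_map: MetricMap | np.ndarray, percent: float = 1.0) -> float:
    """Mean of the highest ``ceil(percent/100 * n)`` non-missing values."""
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    values = (
        metric_map.finite_values()
        if isinstance(metric_map, MetricMap)
        else np.asarray(metric_map, dtype=np.float64)
    )
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no non-missing searchlight values")
    n_top = math.ceil(percent / 100.0 * values.size)
    top = np.sort(values)[-n_top:]
    return float(top.mean())


def _nonzero_shifts(t: int, shift_unit: int, n_shifts: int) -> list[int]:
    shifts = []
    for m in range(1, n_shifts + 1):
        s = m * shift_unit
        if s % t == 0:
            logger.warning("shift %d is a multiple of t=%d; skipped", s, t)
            continue
        shifts.append(s)
    if not shifts:
        raise ValueError("all requested shifts were multiples of t")
    return shifts


def rolling_null_chance(
    data,
    features: FeatureSeries | np.ndarray,
    neighborhoods: NeighborhoodMap,
    kernel: str | Callable = "rsa",
    shift_unit: int = 10,
    n_shifts: int = 100,
    percent: float = 1.0,
    buffer_trs: int = 10,
    kernel_args: Mapping | None = None,
) -> NullSummary:
    """Chance level from temporal misalignment of the model features.

    For each shift s in {shift_unit, 2*shift_unit, ...} the features are
    rolled circularly by s, the searchlight map is recomputed, and its
    top-percent summary recorded; chance is the mean over shifts. Shifts
    that are multiples of t (identity) are skipped with a warning. With
    ``kernel="rsa"`` the brain RSMs are computed once and reused across
    shifts.
    """
    if shift_unit < 1 or n_shifts < 1:
        raise ValueError("shift_unit and n_shifts must be >= 1")
    feat = features.values if isinstance(features, FeatureSeries) else np.asarray(features)
    t = feat.shape[1]
    shifts = _nonzero_shifts(t, shift_unit, n_shifts)
    if kernel == "rsa":
        maps = run_rsa_searchlight(
            data, neighborhoods, features, buffer_trs=buffer_trs, shifts=shifts
        )
        values = [top_percent_summary(maps[s], percent) for s in shifts]
    else:
        values = []
        for s in shifts:
            rolled = np.roll(feat, s, axis=1)
            args = dict(kernel_args or {})
            args["features"] = rolled
            m = run_searchlight(data, neighborhoods, kernel, kernel_args=args)
            values.append(top_percent_summary(m, percent))
    return NullSummary.from_values(values, shifts)


def percent_improvement(
    func_stat: float, anat_stat: float, func_chance: float = 0.0, anat_chance: float = 0.0
) -> float:
    """Chance-corrected percent improvement of functional over anatomical."""
    denom = anat_stat - anat_chance
    if denom == 0:
        raise ZeroDivisionError(
            f"anatomical statistic equals its chance level ({anat_stat}); "
            "percent improvement undefined"
        )
    return 100.0 * ((func_stat - func_chance) - denom) / denom


def bootstrap_improvement(
    per_subject: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> ImprovementSummary:
    """Bootstrap the group mean improvement by resampling subjects.

    Subjects are resampled with replacement ``n_boot`` times; the CI is the
    [2.5th, 97.5th] percentile of resampled means and the one-sided p-value
    is the fraction of means <= 0 (floored at 1/n_boot rather than 0).
    """
    vals = np.asarray(per_subject, dtype=np.float64)
    if vals.size < 1 or n_boot < 1:
        raise ValueError("need >= 1 subject and n_boot >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[draws].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    p = float(np.mean(means <= 0))
    return ImprovementSummary(
        per_subject_improvement=vals,
        mean=float(vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=max(p, 1.0 / n_boot),
        n_boot=n_boot,
    )


def contribution_map(
    metric_maps: Sequence[MetricMap],
    neighborhood_maps: Sequence[NeighborhoodMap],
    n_voxels: int,
    percent: float = 1.0,
    mode: str = "members",
) -> np.ndarray:
    """Across-subject count of voxels contributing to top-percent searchlights.

    For each subject, the top ``percent`` of centers is selected; a voxel
    contributes if it is a member of (mode="members") or the center of
    (mode="centers") at least one such searchlight. Returns the per-voxel
    subject count in the aligned voxel space of size ``n_voxels``.
    """
    if mode not in ("members", "centers"):
        raise ValueError("mode must be 'members' or 'centers'")
    counts = np.zeros(n_voxels, dtype=np.intp)
    for mmap, nmap in zip(metric_maps, neighborhood_maps):
        finite = np.isfinite(mmap.values)
        n_top = math.ceil(percent / 100.0 * finite.sum())
        order = np.argsort(mmap.values[finite])[::-1][:n_top]
        top_idx = np.flatnonzero(finite)[order]
        contributed = np.zeros(n_voxels, dtype=bool)
        for ci in top_idx:
            if mode == "centers":
                contributed[mmap.centers[ci]] = True
            else:
                contributed[nmap.members[ci]] = True
        counts += contributed
    return counts


def median_anatomical_distance(
    member_ids: Sequence[int] | np.ndarray, coords: np.ndarray
) -> float:
    """Median pairwise Euclidean distance (voxel units) among members."""
    member_ids = np.asarray(member_ids, dtype=np.intp)
    if member_ids.size < 2:
        raise ValueError("need at least 2 members")
    pts = np.asarray(coords, dtype=np.float64)[member_ids]
    return float(np.median(pdist(pts)))


def compare_functional_spaces(
    coords_a: FunctionalCoordinates,
    coords_b: FunctionalCoordinates,
    n_pairs: int = 10_000,
    n_samples: int = 1_000,
    n_perm: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Similarity of two functional spaces via voxel-pair distance correlation.

    Repeatedly samples ``n_pairs`` voxel pairs shared by both spaces,
    correlates the two spaces' Euclidean pair distances, and averages over
    ``n_samples`` draws. The permutation p-value relabels space B's voxels
    ``n_perm`` times, each time correlating one fresh pair sample.
    """
    shared, ia, ib = np.intersect1d(coords_a.voxel_ids, coords_b.voxel_ids, return_indices=True)
    if shared.size < 3:
        raise ValueError("fewer than 3 voxels shared between the spaces")
    a = coords_a.coords[ia]
    b = coords_b.coords[ib]
    rng = np.random.default_rng(seed)

    def pair_corr(bmat: np.ndarray) -> float:
        i = rng.integers(0, shared.size, size=n_pairs)
        j = rng.integers(0, shared.size - 1, size=n_pairs)
        j = np.where(j >= i, j + 1, j)  # distinct voxels per pair
        da = np.linalg.norm(a[i] - a[j], axis=1)
        db = np.linalg.norm(bmat[i] - bmat[j], axis=1)
        return float(np.corrcoef(da, db)[0, 1])

    observed = float(np.mean([pair_corr(b) for _ in range(n_samples)]))
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = pair_corr(b[rng.permutation(shared.size)])
    p_value = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return observed, p_value
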