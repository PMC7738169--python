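"""Searchlight engine: map a kernel over every neighborhood deterministically.

``run_searchlight`` is the generic path: any callable over a (members x t)
pattern block. ``run_rsa_searchlight`` is a specialized vectorized path for
the RSA kernel that computes each searchlight's brain RSM once and reuses it
for every temporal misalignment of the model features (the rolling null),
since shifting the features leaves the brain RSMs untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .kernels import FeatureSeries, retained_pair_mask
from .neighborhoods import NeighborhoodMap
from .volume_io import BrainMask, MaskedBold, save_metric_map

logger = logging.getLogger(__name__)

__all__ = ["MetricMap", "run_searchlight", "run_rsa_searchlight", "metric_map_to_table"]

MAX_FAILURE_FRACTION = 0.10


@dataclass(frozen=True)
class MetricMap:
    """Per-center scalar results of one searchlight analysis.

    ``values`` aligns with ``centers``; failed centers hold NaN and carry a
    reason string in ``missing``.
    """

    centers: np.ndarray  # (n,) voxel ids
    values: np.ndarray  # (n,) float, NaN = missing
    kernel_label: str
    kind: str  # "anatomical" | "functional"
    missing: Mapping[int, str] = field(default_factory=dict)

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def as_dict(self, drop_missing: bool = True) -> dict[int, float]:
        out = {}
        for c, v in zip(self.centers, self.values):
            if drop_missing and not np.isfinite(v):
                continue
            out[int(c)] = float(v)
        return out

    def save(self, mask: BrainMask, out_path: str | Path) -> None:
        save_metric_map(self.as_dict(), mask, out_path)


def _eval_center(
    data: np.ndarray,
    members: np.ndarray,
    kernel: Callable[..., float],
    kernel_args: Mapping,
) -> tuple[float, str | None]:
    try:
        return float(kernel(data[members], **kernel_args)), None
    except Exception as exc:  # recorded, not fatal
        return np.nan, f"{type(exc).__name__}: {exc}"


def run_searchlight(
    data: MaskedBold | np.ndarray,
    neighborhoods: NeighborhoodMap,
    kernel: Callable[..., float],
    kernel_args: Mapping | None = None,
    n_workers: int = 1,
    kernel_label: str | None = None,
) -> MetricMap:
    """Apply ``kernel(patterns, **kernel_args)`` at every searchlight center.

    Results are independent of ``n_workers`` and of evaluation order. A
    failing center is recorded as missing with its reason; more than 10%
    failures aborts the run. Kernels must treat the data as read-only.
    """
    mat = data.data if isinstance(data, MaskedBold) else np.asarray(data)
    kernel_args = dict(kernel_args or {})
    label = kernel_label or getattr(kernel, "__name__", "kernel")
    if n_workers == 1:
        results = [
            _eval_center(mat, m, kernel, kernel_args) for m in neighborhoods.members
        ]
    else:
        results = Parallel(n_jobs=n_workers, batch_size=256)(
            delayed(_eval_center)(mat, m, kernel, kernel_args)
            for m in neighborhoods.members
        )
    values = np.array([r[0] for r in results], dtype=np.float64)
    missing = {
        int(c): reason
        for c, (_, reason) in zip(neighborhoods.centers, results)
        if reason is not None
    }
    if missing:
        logger.warning("%d/%d searchlights failed", len(missing), len(results))
    if len(missing) > MAX_FAILURE_FRACTION * len(results):
        raise RuntimeError(
            f"{len(missing)}/{len(results)} searchlight kernels failed "
            f"(> {MAX_FAILURE_FRACTION:.0%}); first reasons: "
            f"{list(missing.values())[:3]}"
        )
    return MetricMap(
        centers=neighborhoods.centers.copy(),
        values=values,
        kernel_label=label,
        kind=neighborhoods.kind,
        missing=missing,
    )


def _standardize_rows(v: np.ndarray) -> np.ndarray:
    v = v - v.mean(axis=-1, keepdims=True)
    sd = v.std(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / sd


def run_rsa_searchlight(
    data: MaskedBold | np.ndarray,
    neighborhoods: NeighborhoodMap,
    features: FeatureSeries | np.ndarray,
    buffer_trs: int = 10,
    shifts: Iterable[int] = (0,),
    batch: int = 256,
) -> dict[int, MetricMap]:
    """RSA searchlight maps for several circular shifts of the model features.

    For each center, the brain RSM's retained (buffered upper-triangular)
    entries are computed once; the per-shift statistic is their Pearson
    correlation with the retained entries of the model RSM built from the
    features rolled by that shift. Centers are processed in batches grouped
    by neighborhood size so the RSM computation is a single batched matrix
    product.
    """
    mat = data.data if isinstance(data, MaskedBold) else np.asarray(data, dtype=np.float64)
    feat = features.values if isinstance(features, FeatureSeries) else np.asarray(features)
    t = mat.shape[1]
    if feat.shape[1] != t:
        raise ValueError(f"features have {feat.shape[1]} TRs, brain data {t}")
    mask = retained_pair_mask(t, buffer_trs)
    flat_idx = np.flatnonzero(mask.ravel())
    shifts = list(shifts)

    # standardized retained model vectors, one per shift
    model_vecs = np.empty((len(shifts), flat_idx.size))
    for si, s in enumerate(shifts):
        rolled = np.roll(feat, s, axis=1)
        rsm = np.corrcoef(rolled.T)  # (t, t) across feature units
        model_vecs[si] = rsm.ravel()[flat_idx]
    model_vecs = _standardize_rows(model_vecs)

    n = neighborhoods.n_centers
    sizes = neighborhoods.sizes()
    stats = np.full((n, len(shifts)), np.nan)
    missing: dict[int, str] = {}
    order = np.argsort(sizes, kind="stable")
    for g_start in range(0, n, batch):
        g = order[g_start : g_start + batch]
        # split the batch into runs of equal neighborhood size
        for size in np.unique(sizes[g]):
            idx = g[sizes[g] == size]
            if size < 2:
                for c in idx:
                    missing[int(neighborhoods.centers[c])] = "fewer than 2 members"
                continue
            block = np.empty((len(idx), size, t), dtype=np.float32)  # (B, m, t)
            for bi, c in enumerate(idx):
                block[bi] = mat[neighborhoods.members[c]]
            mean = block.mean(axis=1, keepdims=True)
            sd = block.std(axis=1, keepdims=True)
            degenerate = (sd == 0).any(axis=(1, 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                zb = (block - mean) / sd
            rsms = np.matmul(zb.transpose(0, 2, 1), zb) / np.float32(size)
            vecs = rsms.reshape(len(idx), -1)[:, flat_idx].astype(np.float64)
            vecs = _standardize_rows(vecs)
            corr = vecs @ model_vecs.T / flat_idx.size  # (B, n_shifts)
            for bi, c in enumerate(idx):
                if degenerate[bi] or not np.all(np.isfinite(corr[bi])):
                    missing[int(neighborhoods.centers[c])] = "degenerate pattern"
                else:
                    stats[c] = corr[bi]
    if len(missing) > MAX_FAILURE_FRACTION * n:
        raise RuntimeError(f"{len(missing)}/{n} RSA searchlights degenerate")
    label = features.label if isinstance(features, FeatureSeries) else "rsa"
    return {
        s: MetricMap(
            centers=neighborhoods.centers.copy(),
            values=stats[:, si].copy(),
            kernel_label=f"rsa:{label}",
            kind=neighborhoods.kind,
            missing=dict(missing),
        )
        for si, s in enumerate(shifts)
    }


def metric_map_to_table(m: MetricMap, path: str | Path | None = None) -> pd.DataFrame:
    """(center_id, value, status) audit table for one metric map."""
    status = np.where(np.isfinite(m.values), "ok", "missing")
    df = pd.DataFrame({"center_id": m.centers, "value": m.values, "status": status})
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
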