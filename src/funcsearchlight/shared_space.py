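"""Learning the functional space: shared response model (SRM) and PCA.

The SRM factorizes each subject's voxel x time matrix as ``X_i = W_i S + E_i``
with orthonormal per-subject bases ``W_i`` (v_i x k) and one shared latent
timecourse ``S`` (k x t), fitted by alternating least squares so that the sum
of squared Frobenius residuals decreases monotonically. A voxel's row of
``W_i`` gives its coordinates in the k-dimensional functional space.

For single-subject designs the same coordinates can come from PCA: the top-k
left singular vectors of the (already time-centered) voxel x time matrix.

``time_segment_matching`` is the model-selection procedure for k: can a
held-out subject's short time window be located within the group's shared
response?
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .volume_io import MaskedBold

__all__ = [
    "SharedSpaceModel",
    "PcaSpaceModel",
    "fit_srm",
    "transform_to_shared",
    "fit_pca_space",
    "time_segment_matching",
    "save_shared_space",
    "load_shared_space",
]


@dataclass(frozen=True)
class SharedSpaceModel:
    """Fitted SRM: per-subject orthonormal bases and the shared timecourse."""

    bases: tuple[np.ndarray, ...]  # each (v_i, k), orthonormal columns
    shared: np.ndarray  # (k, t)
    k: int
    n_subjects: int
    objective_trace: tuple[float, ...]
    subject_ids: tuple[str, ...]

    def basis_for(self, subject: int | str) -> np.ndarray:
        return self.bases[self._index(subject)]

    def _index(self, subject: int | str) -> int:
        if isinstance(subject, str):
            try:
                return self.subject_ids.index(subject)
            except ValueError:
                raise IndexError(f"unknown subject id {subject!r}") from None
        if not 0 <= subject < self.n_subjects:
            raise IndexError(f"subject index {subject} out of range")
        return subject


@dataclass(frozen=True)
class PcaSpaceModel:
    """Single-subject functional space from the top-k principal axes."""

    components: np.ndarray  # (v, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), non-increasing

    @property
    def k(self) -> int:
        return int(self.components.shape[1])


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # Seed derived from the subject identity, not list position, so fits are
    # invariant to subject ordering.
    tag = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _as_matrix(d: MaskedBold | np.ndarray) -> np.ndarray:
    return d.data if isinstance(d, MaskedBold) else np.asarray(d, dtype=np.float64)


def _subject_id(d: MaskedBold | np.ndarray, i: int) -> str:
    return d.subject_id if isinstance(d, MaskedBold) else f"subject{i}"


def fit_srm(
    datasets: Sequence[MaskedBold | np.ndarray],
    k: int,
    n_iter: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
) -> SharedSpaceModel:
    """Fit a deterministic shared response model by alternating updates.

    ``S <- (1/n) sum_i W_i^T X_i`` (least squares given orthonormal bases)
    alternates with the orthogonal Procrustes update ``W_i <- U V^T`` from the
    SVD of ``X_i S^T``. Bases are initialized from the QR factorization of a
    seeded standard-normal matrix per subject. Stops after ``n_iter``
    iterations or when the relative decrease of the squared-residual
    objective falls below ``tol``.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    mats = [_as_matrix(d) for d in datasets]
    t = mats[0].shape[1]
    if any(m.shape[1] != t for m in mats):
        raise ValueError("all subjects must share the same number of TRs")
    kmax = min(min(m.shape[0] for m in mats), t)
    if not 1 <= k <= kmax:
        raise ValueError(f"k={k} must be in [1, {kmax}] (min over subjects of v, t)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    ids = tuple(_subject_id(d, i) for i, d in enumerate(datasets))
    bases = []
    for sid, m in zip(ids, mats):
        rng = _subject_rng(seed, sid)
        q, _ = np.linalg.qr(rng.standard_normal((m.shape[0], k)))
        bases.append(q)

    sq_norms = sum(float(np.sum(m * m)) for m in mats)
    trace: list[float] = []
    shared = np.zeros((k, t))
    for _ in range(n_iter):
        shared = sum(w.T @ m for w, m in zip(bases, mats)) / len(mats)
        for i, m in enumerate(mats):
            u, _, vt = np.linalg.svd(m @ shared.T, full_matrices=False)
            bases[i] = u @ vt
        # sum_i ||X_i - W_i S||_F^2, expanded to avoid forming residuals
        obj = sq_norms + len(mats) * float(np.sum(shared * shared))
        obj -= 2 * sum(float(np.sum((w.T @ m) * shared)) for w, m in zip(bases, mats))
        trace.append(obj)
        if len(trace) >= 2 and trace[-2] - trace[-1] <= tol * max(trace[-2], 1e-300):
            break
    # S consistent with the final bases
    shared = sum(w.T @ m for w, m in zip(bases, mats)) / len(mats)
    return SharedSpaceModel(
        bases=tuple(bases),
        shared=shared,
        k=k,
        n_subjects=len(mats),
        objective_trace=tuple(trace),
        subject_ids=ids,
    )


def transform_to_shared(
    model: SharedSpaceModel,
    dataset: MaskedBold | np.ndarray,
    subject: int | str,
) -> np.ndarray:
    """Project new data for one subject into the shared space: ``W_i^T X``."""
    w = model.basis_for(subject)
    x = _as_matrix(dataset)
    if x.shape[0] != w.shape[0]:
        raise ValueError(
            f"dataset has {x.shape[0]} voxels but subject basis expects {w.shape[0]}"
        )
    return w.T @ x


def fit_pca_space(dataset: MaskedBold | np.ndarray, k: int) -> PcaSpaceModel:
    """Top-k principal axes of the voxel x time matrix.

    Computed as the left singular vectors of the data matrix without
    re-centering: voxels are expected to be z-scored in time (rows centered),
    so this equals PCA of the time x voxel data while keeping the voxel-pair
    cosine structure exactly invariant to orthogonal rotation of the time
    axis. Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    x = _as_matrix(dataset)
    v, t = x.shape
    if not 1 <= k <= min(v, t):
        raise ValueError(f"k={k} must be in [1, {min(v, t)}]")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    u = u[:, :k]
    s = s[:k]
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    u = u * signs
    explained = s**2 / max(t - 1, 1)
    return PcaSpaceModel(components=u, explained_variance=explained)


def time_segment_matching(
    datasets: Sequence[MaskedBold | np.ndarray],
    k: int,
    window_seconds: float = 14.0,
    tr_seconds: float | None = None,
    n_iter: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-subject-out time-segment matching accuracy.

    The SRM is fit on the first half of the timepoints; the second half of
    every subject's data is projected into the shared space. For each
    left-out subject, each sliding test window (flattened k x w block) is
    correlated with every candidate window of the average of the remaining
    subjects' projections; candidates overlapping the test window are
    excluded. Accuracy per subject is the fraction of windows whose best
    match is the correct position.
    """
    if len(datasets) < 2:
        raise ValueError("time-segment matching needs at least 2 subjects")
    if tr_seconds is None:
        trs = {d.tr_seconds for d in datasets if isinstance(d, MaskedBold)}
        tr_seconds = trs.pop() if len(trs) == 1 else 1.0
    mats = [_as_matrix(d) for d in datasets]
    t = mats[0].shape[1]
    t_train = t // 2
    t_test = t - t_train
    w = int(round(window_seconds / tr_seconds))
    if not 1 <= w < t_test:
        raise ValueError(f"window of {w} TRs must be shorter than the test split ({t_test})")

    model = fit_srm([m[:, :t_train] for m in mats], k=k, n_iter=n_iter, seed=seed)
    proj = np.stack(
        [transform_to_shared(model, m[:, t_train:], i) for i, m in enumerate(mats)]
    )  # (n, k, t_test)

    n = len(mats)
    n_windows = t_test - w + 1
    accuracies = np.zeros(n)
    for left_out in range(n):
        test = proj[left_out]
        ref = proj[np.arange(n) != left_out].mean(axis=0)
        # flattened, standardized windows for both series
        test_win = _window_stack(test, w)
        ref_win = _window_stack(ref, w)
        corr = test_win @ ref_win.T  # (n_windows, n_windows)
        correct = 0
        for p in range(n_windows):
            row = corr[p].copy()
            lo, hi = max(0, p - w + 1), min(n_windows, p + w)
            overlap = np.ones(n_windows, dtype=bool)
            overlap[lo:hi] = False
            overlap[p] = True  # the correct candidate always competes
            row[~overlap] = -np.inf
            if int(np.argmax(row)) == p:
                correct += 1
        accuracies[left_out] = correct / n_windows
    return accuracies


def _window_stack(series: np.ndarray, w: int) -> np.ndarray:
    """Flattened sliding windows of a (k, t) series, standardized per window."""
    k, t = series.shape
    n_windows = t - w + 1
    out = np.empty((n_windows, k * w))
    for p in range(n_windows):
        seg = series[:, p : p + w].ravel()
        seg = seg - seg.mean()
        nrm = np.linalg.norm(seg)
        out[p] = seg / nrm if nrm > 0 else seg
    return out


def save_shared_space(model: SharedSpaceModel, path: str | Path) -> None:
    arrays = {f"basis_{i}": b for i, b in enumerate(model.bases)}
    np.savez_compressed(
        str(path),
        shared=model.shared,
        k=np.intp(model.k),
        objective_trace=np.asarray(model.objective_trace),
        subject_ids=np.asarray(model.subject_ids),
        **arrays,
    )


def load_shared_space(path: str | Path) -> SharedSpaceModel:
    with np.load(str(path)) as npz:
        ids = tuple(str(s) for s in npz["subject_ids"])
        bases = tuple(npz[f"basis_{i}"] for i in range(len(ids)))
        return SharedSpaceModel(
            bases=bases,
            shared=npz["shared"],
            k=int(npz["k"]),
            n_subjects=len(ids),
            objective_trace=tuple(float(x) for x in npz["objective_trace"]),
            subject_ids=ids,
        )
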