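"""Per-searchlight computations: RSA, embedding decoding, category decoding.

Each kernel consumes a (members x TRs) pattern block extracted by the engine
and returns one scalar, the value assigned to the searchlight's center voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .volume_io import MaskedBold

__all__ = [
    "FeatureSeries",
    "BufferedRsm",
    "LocalizerDesign",
    "buffered_rsm",
    "rsa_similarity",
    "embedding_decode",
    "bin_ranking_accuracy",
    "category_decode",
    "design_from_events",
    "load_feature_series",
]


@dataclass(frozen=True)
class FeatureSeries:
    """A model's feature x TR activity matrix (DNN layer, embeddings, ...)."""

    values: np.ndarray  # (f, t)
    label: str = "features"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("feature values must be (features x TRs)")
        object.__setattr__(self, "values", vals)

    @property
    def n_features(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_trs(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class BufferedRsm:
    """Timepoint x timepoint correlation matrix with an autocorrelation buffer.

    Only upper-triangular pairs separated by more than ``buffer_trs`` TRs are
    retained for second-order comparison; pairs inside the diagonal band are
    masked out because BOLD autocorrelation inflates their similarity.
    """

    rsm: np.ndarray  # (t, t) symmetric, unit diagonal
    buffer_trs: int
    retained_mask: np.ndarray  # boolean (t, t), upper-triangular beyond buffer

    @property
    def retained_values(self) -> np.ndarray:
        return self.rsm[self.retained_mask]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())


def retained_pair_mask(t: int, buffer_trs: int) -> np.ndarray:
    """Upper-triangular mask of TR pairs with |i - j| > buffer_trs."""
    idx = np.arange(t)
    return (idx[None, :] - idx[:, None]) > buffer_trs


def buffered_rsm(patterns: np.ndarray, buffer_trs: int = 10) -> BufferedRsm:
    """Correlate activity patterns across TRs, masking the diagonal band.

    ``patterns`` is (members x t); the RSM entry (i, j) is the Pearson
    correlation of the member patterns at TRs i and j.
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("patterns must be (members x TRs) with >= 2 members")
    t = patterns.shape[1]
    if buffer_trs < 0 or t <= buffer_trs + 1:
        raise ValueError(f"need t > buffer_trs + 1 (t={t}, buffer={buffer_trs})")
    stds = patterns.std(axis=0)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise ValueError(f"constant pattern at TR(s) {bad.tolist()}: correlation undefined")
    rsm = np.corrcoef(patterns.T)
    return BufferedRsm(rsm=rsm, buffer_trs=buffer_trs, retained_mask=retained_pair_mask(t, buffer_trs))


def rsa_similarity(brain_rsm: BufferedRsm, model_rsm: BufferedRsm) -> float:
    """Second-order similarity: correlate retained entries of two RSMs."""
    if brain_rsm.rsm.shape != model_rsm.rsm.shape:
        raise ValueError("RSMs must share t")
    if brain_rsm.buffer_trs != model_rsm.buffer_trs:
        raise ValueError("RSMs must share the buffer")
    a = brain_rsm.retained_values
    b = model_rsm.retained_values
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in retained RSM entries")
    return float(np.corrcoef(a, b)[0, 1])


def bin_ranking_accuracy(
    predicted: np.ndarray, actual: np.ndarray, n_bins: int = 25
) -> float:
    """Scene-ranking score: fraction of predicted bins matched to themselves.

    Predicted and actual (t x f) vector series are averaged within
    ``n_bins`` consecutive-TR bins; the accuracy is the fraction of rows of
    the bin x bin correlation matrix whose argmax lies on the diagonal.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if predicted.shape != actual.shape:
        raise ValueError("predicted/actual shape mismatch")
    t = predicted.shape[0]
    if t % n_bins != 0:
        raise ValueError(f"t={t} not divisible by n_bins={n_bins}")
    pred_b = predicted.reshape(n_bins, t // n_bins, -1).mean(axis=1)
    act_b = actual.reshape(n_bins, t // n_bins, -1).mean(axis=1)
    pz = pred_b - pred_b.mean(axis=1, keepdims=True)
    az = act_b - act_b.mean(axis=1, keepdims=True)
    if np.any(np.linalg.norm(pz, axis=1) == 0) or np.any(np.linalg.norm(az, axis=1) == 0):
        raise ValueError("constant bin vector: correlation undefined")
    pz /= np.linalg.norm(pz, axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    m = pz @ az.T
    return float(np.mean(np.argmax(m, axis=1) == np.arange(n_bins)))


def embedding_decode(
    train_brain: np.ndarray,
    train_embeddings: np.ndarray,
    test_brain: np.ndarray,
    test_embeddings: np.ndarray,
    ridge_penalty: float = 1.0,
    n_bins: int = 25,
) -> float:
    """Ridge-decode embedding vectors from searchlight activity, bin-ranked.

    Brain blocks are (members x t); embeddings are (f x t). A ridge map from
    voxels to embedding dimensions is fit on the training TRs and applied to
    the test TRs; accuracy is :func:`bin_ranking_accuracy` over ``n_bins``
    consecutive-TR bins of the test set.
    """
    xb = np.asarray(train_brain, dtype=np.float64).T  # (t1, m)
    yb = np.asarray(train_embeddings, dtype=np.float64).T  # (t1, f)
    xt = np.asarray(test_brain, dtype=np.float64).T
    yt = np.asarray(test_embeddings, dtype=np.float64).T
    if xb.shape[0] != yb.shape[0] or xt.shape[0] != yt.shape[0]:
        raise ValueError("brain/embedding TR counts must match")
    if yb.shape[1] != yt.shape[1]:
        raise ValueError("train/test embedding dimension mismatch")
    model = Ridge(alpha=ridge_penalty)
    model.fit(xb, yb)
    pred = model.predict(xt)
    if not np.all(np.isfinite(model.coef_)):
        raise FloatingPointError("non-finite ridge coefficients")
    return bin_ranking_accuracy(pred, yt, n_bins=n_bins)


@dataclass(frozen=True)
class LocalizerDesign:
    """Block-design localizer examples for category decoding.

    One row of ``examples`` per block (averaged voxel pattern), with its
    category label and run id. Category counts must be balanced so stratified
    folds contain every category.
    """

    examples: np.ndarray  # (e, v)
    labels: np.ndarray  # (e,) category per example
    run_ids: np.ndarray  # (e,)

    def __post_init__(self) -> None:
        ex = np.asarray(self.examples, dtype=np.float64)
        labels = np.asarray(self.labels)
        runs = np.asarray(self.run_ids)
        if ex.ndim != 2 or labels.shape != (ex.shape[0],) or runs.shape != (ex.shape[0],):
            raise ValueError("examples/labels/run_ids sizes disagree")
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() != counts.max():
            raise ValueError("category example counts must be balanced")
        object.__setattr__(self, "examples", ex)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "run_ids", runs)

    @property
    def n_categories(self) -> int:
        return int(np.unique(self.labels).size)


def category_decode(
    design: LocalizerDesign,
    member_ids: Sequence[int] | np.ndarray,
    n_folds: int = 3,
) -> float:
    """Stratified n-fold linear-SVM category decoding on a voxel subset.

    Returns the mean cross-validated accuracy; chance is 1 / n_categories
    because folds are stratified.
    """
    member_ids = np.asarray(member_ids, dtype=np.intp)
    x = design.examples[:, member_ids]
    y = design.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification impossible: a category has {counts.min()} examples "
            f"for {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    accs = []
    for train_idx, test_idx in skf.split(x, y):
        clf = LinearSVC(C=1.0, max_iter=5000)
        clf.fit(x[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(x[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def design_from_events(
    bold: MaskedBold,
    events: pd.DataFrame,
    hrf_shift_trs: int = 2,
) -> LocalizerDesign:
    """Build block-averaged localizer examples from an events table.

    ``events`` needs columns onset_tr, duration_trs, category, run. Each
    block's example is the mean pattern over its TRs after a fixed
    hemodynamic shift of ``hrf_shift_trs`` TRs.
    """
    required = {"onset_tr", "duration_trs", "category", "run"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    rows, labels, runs = [], [], []
    for _, ev in events.iterrows():
        start = int(ev.onset_tr) + hrf_shift_trs
        stop = start + int(ev.duration_trs)
        if stop > bold.n_trs:
            raise ValueError(f"block at onset {ev.onset_tr} extends past the run")
        rows.append(bold.data[:, start:stop].mean(axis=1))
        labels.append(ev.category)
        runs.append(ev.run)
    return LocalizerDesign(
        examples=np.asarray(rows),
        labels=np.asarray(labels),
        run_ids=np.asarray(runs),
    )


def load_feature_series(path: str | Path, label: str | None = None) -> FeatureSeries:
    """Read a feature x TR matrix from delimited text or an array archive."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(str(path)) as npz:
            key = label if label in npz else "values"
            return FeatureSeries(values=npz[key], label=label or str(npz.get("label", "features")))
    values = np.loadtxt(path, delimiter=None if path.suffix == ".txt" else ",", ndmin=2)
    return FeatureSeries(values=values, label=label or path.stem)
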