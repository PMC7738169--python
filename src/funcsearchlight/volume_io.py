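"""Masked 4-D BOLD volume I/O and the package's coordinate conventions.

All downstream modules identify a voxel by its *voxel id*: the row index of
the voxel in the lexicographically sorted (i, j, k) list of in-mask grid
coordinates. Loading the same volume/mask pair therefore always yields the
same voxel ordering, and metric maps written back to disk place each value
at its id's grid position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BrainMask",
    "MaskedBold",
    "load_masked_bold",
    "save_metric_map",
    "save_masked_bold",
    "load_cached_bold",
    "save_bold_volume",
]


@dataclass(frozen=True)
class BrainMask:
    """A binary brain mask on a 3-D grid.

    Parameters
    ----------
    shape
        Grid dimensions (nx, ny, nz).
    voxels
        Integer array of shape (v, 3): 0-based in-mask grid coordinates,
        lexicographically sorted. Row index == voxel id.
    affine
        Voxel-to-world affine carried through to any output volume,
        never used for resampling.
    """

    shape: tuple[int, int, int]
    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.intp)
        if vox.ndim != 2 or vox.shape[1] != 3:
            raise ValueError("mask voxels must be an (v, 3) integer array")
        if vox.shape[0] == 0:
            raise ValueError("empty brain mask")
        if np.any(vox < 0) or np.any(vox >= np.asarray(self.shape)):
            raise ValueError("mask voxel outside the grid bounds")
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        vox = vox[order]
        if np.any(np.all(np.diff(vox, axis=0) == 0, axis=1)):
            raise ValueError("duplicate voxel coordinates in mask")
        object.__setattr__(self, "voxels", vox)

    @classmethod
    def from_array(cls, mask_array: np.ndarray, affine: np.ndarray | None = None) -> "BrainMask":
        arr = np.asarray(mask_array)
        if arr.ndim != 3:
            raise ValueError("mask array must be 3-D")
        coords = np.argwhere(arr > 0)
        if coords.size == 0:
            raise ValueError("empty brain mask")
        return cls(
            shape=tuple(int(s) for s in arr.shape),
            voxels=coords,
            affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.shape, dtype=np.uint8)
        arr[tuple(self.voxels.T)] = 1
        return arr

    def id_grid(self) -> np.ndarray:
        """Grid of voxel ids, -1 outside the mask."""
        grid = np.full(self.shape, -1, dtype=np.intp)
        grid[tuple(self.voxels.T)] = np.arange(self.n_voxels)
        return grid


@dataclass(frozen=True)
class MaskedBold:
    """One subject's in-mask BOLD activity.

    ``data`` is a (v voxels x t TRs) matrix; row order matches ``coords``
    (lexicographic grid order) and defines the voxel ids used everywhere
    downstream.
    """

    data: np.ndarray
    coords: np.ndarray
    tr_seconds: float
    subject_id: str
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        coords = np.asarray(self.coords, dtype=np.intp)
        if data.ndim != 2:
            raise ValueError("data must be (voxels x TRs)")
        if data.shape[1] < 2:
            raise ValueError("need at least 2 TRs")
        if coords.shape != (data.shape[0], 3):
            raise ValueError("coords must be (v, 3) matching data rows")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "coords", coords)

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_trs(self) -> int:
        return int(self.data.shape[1])

    def zscored(self) -> "MaskedBold":
        """Return a copy with each voxel's time series z-scored.

        Zero-variance voxels are dropped (with a logged count), mirroring
        the exclusion of non-brain/empty voxels at load time.
        """
        data, coords, n_dropped = _zscore_rows(self.data, self.coords)
        if n_dropped:
            logger.info("z-scoring dropped %d zero-variance voxels", n_dropped)
        return replace(self, data=data, coords=coords)


def _zscore_rows(
    data: np.ndarray, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    std = data.std(axis=1)
    keep = std > 0
    n_dropped = int((~keep).sum())
    data = data[keep]
    data = (data - data.mean(axis=1, keepdims=True)) / std[keep][:, None]
    return data, coords[keep], n_dropped


def load_masked_bold(
    volume_path: str | Path,
    mask_path: str | Path,
    zscore: bool = True,
    subject_id: str | None = None,
    tr_seconds: float | None = None,
) -> MaskedBold:
    """Load a 4-D BOLD volume restricted to a 3-D brain mask.

    Voxels are returned in deterministic lexicographic (i, j, k) order. If
    ``zscore`` is set, each voxel's time series is standardized to mean 0 /
    unit variance and zero-variance voxels are excluded (count logged).
    """
    img = nib.load(str(volume_path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {vol.shape}")
    mask_img = nib.load(str(mask_path))
    mask_arr = np.asarray(mask_img.dataobj)
    if mask_arr.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got shape {mask_arr.shape}")
    if vol.shape[:3] != mask_arr.shape:
        raise ValueError(
            f"volume grid {vol.shape[:3]} does not match mask grid {mask_arr.shape}"
        )
    mask = BrainMask.from_array(mask_arr, affine=mask_img.affine)
    data = vol[tuple(mask.voxels.T)]
    coords = mask.voxels.copy()
    if zscore:
        data, coords, n_dropped = _zscore_rows(data, coords)
        if n_dropped:
            logger.info(
                "%s: excluded %d zero-variance voxels at load", volume_path, n_dropped
            )
        if data.shape[0] == 0:
            raise ValueError("all voxels had zero variance")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return MaskedBold(
        data=data,
        coords=coords,
        tr_seconds=tr_seconds,
        subject_id=subject_id or Path(str(volume_path)).stem,
        mask=mask,
    )


def save_metric_map(
    values: dict[int, float],
    mask: BrainMask,
    out_path: str | Path,
) -> None:
    """Write a scalar per-voxel metric into a 3-D volume (background 0).

    Keys are voxel ids in ``mask``'s ordering; a key outside the mask is an
    error. Values round-trip at float32 NIfTI precision.
    """
    vol = np.zeros(mask.shape, dtype=np.float64)
    for vid, val in values.items():
        if not 0 <= vid < mask.n_voxels:
            raise KeyError(f"voxel id {vid} outside the mask (v={mask.n_voxels})")
        i, j, k = mask.voxels[vid]
        vol[i, j, k] = val
    img = nib.Nifti1Image(vol, mask.affine)
    nib.save(img, str(out_path))


def save_bold_volume(bold: MaskedBold, mask: BrainMask, out_path: str | Path) -> None:
    """Write a MaskedBold back to a 4-D volume (background 0)."""
    grid = mask.id_grid()
    ids = grid[tuple(bold.coords.T)]
    if np.any(ids < 0):
        raise ValueError("bold coordinates outside the mask")
    vol = np.zeros(mask.shape + (bold.n_trs,), dtype=np.float64)
    vol[tuple(bold.coords.T)] = bold.data
    nib.save(nib.Nifti1Image(vol, mask.affine), str(out_path))


def save_masked_bold(bold: MaskedBold, out_path: str | Path) -> None:
    """Cache a MaskedBold matrix as a compressed array archive."""
    np.savez_compressed(
        str(out_path),
        data=bold.data,
        coords=bold.coords,
        tr_seconds=np.float64(bold.tr_seconds),
        subject_id=np.str_(bold.subject_id),
    )


def load_cached_bold(path: str | Path) -> MaskedBold:
    with np.load(str(path)) as npz:
        return MaskedBold(
            data=npz["data"],
            coords=npz["coords"],
            tr_seconds=float(npz["tr_seconds"]),
            subject_id=str(npz["subject_id"]),
        )
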