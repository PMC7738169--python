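"""Searchlight neighborhoods: anatomical cubes and functional k-NN.

Both variants produce a :class:`NeighborhoodMap` with the same contract —
an ordered list of member voxel ids per center — so any kernel can run over
either. Anatomical neighborhoods are cubes of side ``2r+1`` intersected with
the brain mask; functional neighborhoods are each voxel plus its ``j``
nearest retained voxels by cosine distance in the learned functional space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shared_space import PcaSpaceModel, SharedSpaceModel
from .volume_io import BrainMask

__all__ = [
    "FunctionalCoordinates",
    "NeighborhoodMap",
    "functional_coordinates",
    "anatomical_neighborhoods",
    "functional_neighborhoods",
    "neighborhoods_to_table",
]


@dataclass(frozen=True)
class FunctionalCoordinates:
    """Voxel coordinates in the learned k-dimensional functional space.

    ``voxel_ids[r]`` is the mask voxel id whose embedding is ``coords[r]``.
    Voxels whose loading row had norm below the zero tolerance are dropped
    (they contribute nothing to the shared space) and listed in
    ``dropped_ids``.
    """

    voxel_ids: np.ndarray  # (m,) retained voxel ids, ascending
    coords: np.ndarray  # (m, k)
    dropped_ids: np.ndarray  # (d,) ascending

    @property
    def n_retained(self) -> int:
        return int(self.voxel_ids.shape[0])

    @property
    def k(self) -> int:
        return int(self.coords.shape[1])


@dataclass(frozen=True)
class NeighborhoodMap:
    """Ordered member voxel ids per searchlight center."""

    centers: np.ndarray  # (n,) voxel ids
    members: tuple[np.ndarray, ...]  # one ordered id array per center
    kind: str  # "anatomical" | "functional"

    def __post_init__(self) -> None:
        if len(self.members) != len(self.centers):
            raise ValueError("one member list required per center")
        if self.kind not in ("anatomical", "functional"):
            raise ValueError(f"unknown neighborhood kind {self.kind!r}")

    @property
    def n_centers(self) -> int:
        return int(len(self.centers))

    def sizes(self) -> np.ndarray:
        return np.array([m.size for m in self.members], dtype=np.intp)


def functional_coordinates(
    model: SharedSpaceModel | PcaSpaceModel,
    subject: int | str = 0,
    zero_tol: float = 1e-12,
) -> FunctionalCoordinates:
    """Re-embed voxels using their loading rows as functional coordinates.

    Rows with Euclidean norm below ``zero_tol`` are discarded: such voxels
    have (numerically) zero weight on every latent dimension.
    """
    if isinstance(model, PcaSpaceModel):
        loadings = model.components
    else:
        loadings = model.basis_for(subject)
    norms = np.linalg.norm(loadings, axis=1)
    keep = norms >= zero_tol
    all_ids = np.arange(loadings.shape[0], dtype=np.intp)
    return FunctionalCoordinates(
        voxel_ids=all_ids[keep],
        coords=np.asarray(loadings[keep], dtype=np.float64),
        dropped_ids=all_ids[~keep],
    )


def anatomical_neighborhoods(mask: BrainMask, radius: int = 3) -> NeighborhoodMap:
    """Cubic searchlights of side ``2*radius + 1`` clipped to the mask.

    Members are ordered lexicographically by grid coordinate. Centers at the
    brain edge keep only their in-mask members, as in standard volumetric
    searchlight practice.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grid = mask.id_grid()
    side = 2 * radius + 1
    offs = np.stack(
        np.meshgrid(*([np.arange(-radius, radius + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)  # lexicographic offset order
    members: list[np.ndarray] = []
    shape = np.asarray(mask.shape)
    for center in mask.voxels:
        pts = center[None, :] + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        ids = grid[tuple(pts[ok].T)]
        members.append(ids[ids >= 0].astype(np.intp))
    assert all(m.size <= side**3 for m in members)
    return NeighborhoodMap(
        centers=np.arange(mask.n_voxels, dtype=np.intp),
        members=tuple(members),
        kind="anatomical",
    )


def functional_neighborhoods(
    coords: FunctionalCoordinates,
    j: int,
    yoke_sizes: Mapping[int, int] | Sequence[int] | None = None,
    chunk: int = 512,
) -> NeighborhoodMap:
    """Cosine k-NN searchlights in functional space.

    Each retained voxel is a center; its members are the center itself
    followed by its ``j`` nearest retained voxels, nearest first, with exact
    cosine distances (``1 - cos``) and ties broken by ascending voxel id.
    ``yoke_sizes`` truncates each ordered member list to a per-center count
    (the control that matches anatomical searchlight sizes exactly).
    """
    m = coords.n_retained
    if not 1 <= j <= m - 1:
        raise ValueError(f"j={j} must be in [1, {m - 1}]")
    x = coords.coords
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    unit = x / norms
    ids = coords.voxel_ids
    members: list[np.ndarray] = []
    if yoke_sizes is not None and not isinstance(yoke_sizes, Mapping):
        yoke_sizes = {int(c): int(s) for c, s in zip(ids, yoke_sizes)}
    for start in range(0, m, chunk):
        block = slice(start, min(start + chunk, m))
        dist = 1.0 - unit[block] @ unit.T  # exact cosine distance
        rows = np.arange(block.stop - block.start)
        dist[rows, rows + block.start] = -np.inf  # center always first
        # exact selection: partition, then resolve boundary ties by ascending id
        part = np.argpartition(dist, j, axis=1)[:, : j + 1]
        dstar = dist[rows[:, None], part].max(axis=1)
        for row_i, global_i in enumerate(range(block.start, block.stop)):
            row = dist[row_i]
            cand = np.flatnonzero(row <= dstar[row_i])
            order = cand[np.lexsort((cand, row[cand]))]  # (distance, id) ascending
            sel = order[: j + 1]
            chosen = ids[sel]
            if yoke_sizes is not None:
                size = yoke_sizes[int(ids[global_i])]
                if not 1 <= size <= chosen.size:
                    raise ValueError(
                        f"yoked size {size} invalid for center {ids[global_i]}"
                    )
                chosen = chosen[:size]
            members.append(chosen.astype(np.intp))
    return NeighborhoodMap(centers=ids.copy(), members=tuple(members), kind="functional")


def neighborhoods_to_table(nmap: NeighborhoodMap, path: str | Path | None = None) -> pd.DataFrame:
    """Long-format (center_id, member_rank, member_id) table for audit."""
    rows = {
        "center_id": np.repeat(nmap.centers, nmap.sizes()),
        "member_rank": np.concatenate([np.arange(m.size) for m in nmap.members]),
        "member_id": np.concatenate(list(nmap.members)),
    }
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
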