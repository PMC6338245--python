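"""Fusion of per-subject selections into group-level sets and the set S.

Phase II of the selection procedure: intersect the per-subject voxel
sets within each group (voxels consistently activated across subjects),
then merge the two group sets into the final feature set
``S = V_S_G1 ∪ V_S_G2``, and backtrack each member of S to world (MNI
mm) coordinates through the scan affine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import voxel_to_world
from .select import SelectionMask

VoxelIndex = tuple[int, int, int]


@dataclass
class GroupSelection:
    """Group-consensus voxel sets and their union S.

    Sets are stored as lexicographically sorted lists of 0-based index
    triples so that serialized outputs are byte-reproducible.
    """

    g1_set: list[VoxelIndex]
    g2_set: list[VoxelIndex]
    union_set: list[VoxelIndex]
    alpha: float
    consensus: float
    grid: tuple[int, int, int]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "consensus": self.consensus,
            "grid": list(self.grid),
            "g1_set": [list(v) for v in self.g1_set],
            "g2_set": [list(v) for v in self.g2_set],
            "union_set": [list(v) for v in self.union_set],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSelection":
        as_idx = lambda lst: [tuple(int(x) for x in v) for v in lst]
        return cls(
            g1_set=as_idx(d["g1_set"]),
            g2_set=as_idx(d["g2_set"]),
            union_set=as_idx(d["union_set"]),
            alpha=float(d["alpha"]),
            consensus=float(d["consensus"]),
            grid=tuple(int(g) for g in d["grid"]),
        )

    def union_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid, dtype=bool)
        if self.union_set:
            vol[tuple(np.array(self.union_set).T)] = True
        return vol


def _sorted_indices(volume: np.ndarray) -> list[VoxelIndex]:
    return [tuple(int(v) for v in ijk) for ijk in np.argwhere(volume)]


def group_consensus(masks: list[SelectionMask], consensus: float = 1.0) -> list[VoxelIndex]:
    """Voxels selected in at least ``ceil(consensus * m)`` of m subjects.

    ``consensus=1.0`` (the default) is exactly the strict group-wise
    intersection. Lower values relax the rule: a voxel survives when a
    sufficient fraction of the group selects it, which keeps one
    non-responding subject from emptying the group set.
    """
    if not masks:
        raise ValueError("group consensus needs at least one subject mask")
    if not 0 < consensus <= 1:
        raise ValueError("consensus must lie in (0, 1]")
    if len({m.grid for m in masks}) > 1:
        raise ValueError("subject masks must share one grid")
    if len({m.alpha for m in masks}) > 1:
        raise ValueError("subject masks must share one alpha")
    m = len(masks)
    need = math.ceil(consensus * m)
    counts = np.sum([mask.selected for mask in masks], axis=0)
    return _sorted_indices(counts >= need)


def fuse_groups(
    g1: list[VoxelIndex],
    g2: list[VoxelIndex],
    grid: tuple[int, int, int],
    alpha: float,
    consensus: float = 1.0,
) -> GroupSelection:
    """Merge the two group-consensus sets into S = g1 ∪ g2."""
    union = sorted(set(map(tuple, g1)) | set(map(tuple, g2)))
    return GroupSelection(
        g1_set=sorted(map(tuple, g1)),
        g2_set=sorted(map(tuple, g2)),
        union_set=union,
        alpha=float(alpha),
        consensus=float(consensus),
        grid=tuple(grid),
    )


def fuse_cohort(
    subject_masks: dict[str, SelectionMask],
    groups: dict[str, str],
    consensus: float = 1.0,
) -> GroupSelection:
    """Group-wise consensus then union, from per-subject selection masks.

    ``groups`` maps subject id -> "G1"/"G2"; both groups must be present.
    """
    g1_masks = [m for sid, m in sorted(subject_masks.items()) if groups[sid] == "G1"]
    g2_masks = [m for sid, m in sorted(subject_masks.items()) if groups[sid] == "G2"]
    if not g1_masks or not g2_masks:
        raise ValueError("both groups must be non-empty for fusion")
    any_mask = next(iter(subject_masks.values()))
    return fuse_groups(
        group_consensus(g1_masks, consensus),
        group_consensus(g2_masks, consensus),
        grid=any_mask.grid,
        alpha=any_mask.alpha,
        consensus=consensus,
    )


def backtrack_coordinates(selection: GroupSelection, affine: np.ndarray) -> pd.DataFrame:
    """One row per voxel of S with its grid index and MNI mm coordinate.

    Rows are ordered lexicographically by grid index, so the table is
    deterministic for a given selection.
    """
    idx = sorted(selection.union_set)
    for ijk in idx:
        if any(c < 0 or c >= g for c, g in zip(ijk, selection.grid)):
            raise IndexError(f"voxel index {ijk} out of bounds for grid {selection.grid}")
    if not idx:
        return pd.DataFrame(columns=["i", "j", "k", "x_mni", "y_mni", "z_mni"])
    arr = np.array(idx, dtype=int)
    mni = voxel_to_world(arr, affine)
    return pd.DataFrame(
        {
            "i": arr[:, 0],
            "j": arr[:, 1],
            "k": arr[:, 2],
            "x_mni": mni[:, 0],
            "y_mni": mni[:, 1],
            "z_mni": mni[:, 2],
        }
    )
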