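"""MNI→Talairach conversion and hierarchical anatomical labelling.

Selected voxels live in MNI space (the grids are spatially normalized to
an MNI template); anatomical region names, however, are conventionally
read off the Talairach stereotaxic atlas. The conversion here is the
widely used two-branch linear approximation: one translation-free 3×3
matrix above the AC plane (z ≥ 0) and one below (z < 0). The two
branches agree on the z = 0 plane, so the map is continuous, and the
origin (anterior commissure) is a fixed point.

Region lookup is deliberately simple and pluggable: an atlas is a CSV of
labelled axis-aligned boxes in Talairach mm, half-open on each axis
(``[min, max)``), carrying four hierarchy levels — hemisphere, lobe,
gyrus and Brodmann area. A coordinate outside every box is labelled
``unlabelled``. A hand-made toy atlas ships with the package for desk
use; a user-supplied full lookup table drops in through the same CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import GroupSelection

#: Two-branch linear MNI→Talairach coefficients (rows act on (x, y, z)).
#: Swap this table to use a different published approximation.
MNI_TO_TAL_ZPOS = np.array(
    [
        [0.9900, 0.0000, 0.0000],
        [0.0000, 0.9688, 0.0460],
        [0.0000, -0.0485, 0.9189],
    ]
)
MNI_TO_TAL_ZNEG = np.array(
    [
        [0.9900, 0.0000, 0.0000],
        [0.0000, 0.9688, 0.0420],
        [0.0000, -0.0485, 0.8390],
    ]
)

UNLABELLED = "unlabelled"

HIERARCHY_LEVELS = ("hemisphere", "lobe", "gyrus", "brodmann_area")

ATLAS_COLUMNS = (
    "xmin",
    "xmax",
    "ymin",
    "ymax",
    "zmin",
    "zmax",
    "hemisphere",
    "lobe",
    "gyrus",
    "brodmann_area",
)


def mni_to_tal(mni_mm) -> np.ndarray:
    """Map MNI mm coordinates to Talairach mm.

    Accepts a single (x, y, z) triple or an (n, 3) array. The branch is
    chosen per point by the sign of z; both branches coincide at z = 0.
    """
    pts = np.asarray(mni_mm, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("MNI coordinates must be finite")
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("coordinates must be (x, y, z) triples")
    out = np.where(
        (pts[:, 2] >= 0)[:, None],
        pts @ MNI_TO_TAL_ZPOS.T,
        pts @ MNI_TO_TAL_ZNEG.T,
    )
    return out[0] if single else out


@dataclass
class AtlasTable:
    """Region lookup table of labelled half-open boxes in Talairach mm."""

    boxes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.boxes.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        if len(self.boxes) == 0:
            raise ValueError("atlas table has no regions")

    def lookup(self, tal_mm) -> dict[str, str]:
        """Labels for one Talairach point; first containing box wins."""
        x, y, z = (float(v) for v in tal_mm)
        b = self.boxes
        hit = b[
            (b.xmin <= x) & (x < b.xmax)
            & (b.ymin <= y) & (y < b.ymax)
            & (b.zmin <= z) & (z < b.zmax)
        ]
        if len(hit) == 0:
            return {level: UNLABELLED for level in HIERARCHY_LEVELS}
        row = hit.iloc[0]
        return {level: str(row[level]) for level in HIERARCHY_LEVELS}


def load_atlas(path: str | Path) -> AtlasTable:
    """Read an atlas CSV (half-open boxes in Talairach mm + four labels)."""
    return AtlasTable(pd.read_csv(path))


def toy_atlas() -> AtlasTable:
    """A small synthetic stand-in atlas for desk-scale work and tests.

    Eight coarse boxes tile a ±75 mm cube around the origin, split by
    hemisphere (x), front/back (y) and top/bottom (z), with plausible
    (but deliberately coarse and synthetic) lobe/gyrus/Brodmann labels.
    It exercises the lookup interface; it does not reproduce the real
    Talairach atlas.
    """
    rows = []
    labels = {
        # (x>=0 right, y>=0 front, z>=0 top) -> (lobe, gyrus, BA)
        (1, 1, 1): ("Frontal Lobe", "Superior Frontal Gyrus", "BA 10"),
        (0, 1, 1): ("Frontal Lobe", "Medial Frontal Gyrus", "BA 9"),
        (1, 0, 1): ("Parietal Lobe", "Precuneus", "BA 7"),
        (0, 0, 1): ("Occipital Lobe", "Cuneus", "BA 18"),
        (1, 1, 0): ("Temporal Lobe", "Superior Temporal Gyrus", "BA 22"),
        (0, 1, 0): ("Temporal Lobe", "Middle Temporal Gyrus", "BA 21"),
        (1, 0, 0): ("Occipital Lobe", "Lingual Gyrus", "BA 19"),
        (0, 0, 0): ("Occipital Lobe", "Middle Occipital Gyrus", "BA 17"),
    }
    for (right, front, top), (lobe, gyrus, ba) in labels.items():
        rows.append(
            {
                "xmin": 0.0 if right else -75.0,
                "xmax": 75.0 if right else 0.0,
                "ymin": 0.0 if front else -75.0,
                "ymax": 75.0 if front else 0.0,
                "zmin": 0.0 if top else -75.0,
                "zmax": 75.0 if top else 0.0,
                "hemisphere": "Right" if right else "Left",
                "lobe": lobe,
                "gyrus": gyrus,
                "brodmann_area": ba,
            }
        )
    return AtlasTable(pd.DataFrame(rows))


def label_coordinates(table: pd.DataFrame, atlas: AtlasTable) -> pd.DataFrame:
    """Fill Talairach coordinates and region labels into a coordinate table.

    ``table`` must carry ``x_mni, y_mni, z_mni`` columns (as produced by
    ``fusion.backtrack_coordinates``); the result adds ``x_tal, y_tal,
    z_tal`` plus one column per hierarchy level. Deterministic for a
    fixed atlas.
    """
    out = table.copy()
    if len(out) == 0:
        for c in ("x_tal", "y_tal", "z_tal", *HIERARCHY_LEVELS):
            out[c] = pd.Series(dtype=float if c.startswith(("x", "y", "z")) else str)
        return out
    tal = mni_to_tal(out[["x_mni", "y_mni", "z_mni"]].to_numpy())
    out["x_tal"], out["y_tal"], out["z_tal"] = tal[:, 0], tal[:, 1], tal[:, 2]
    labels = [atlas.lookup(p) for p in tal]
    for level in HIERARCHY_LEVELS:
        out[level] = [lab[level] for lab in labels]
    return out


def region_summary(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Voxel counts per region label at one hierarchy level.

    ``level`` is one of hemisphere / lobe / gyrus / brodmann (the latter
    an alias for ``brodmann_area``). Counts sum to the number of rows,
    the ``unlabelled`` bucket included; sorted by descending count, ties
    broken alphabetically.
    """
    col = "brodmann_area" if level in ("brodmann", "brodmann_area") else level
    if col not in HIERARCHY_LEVELS:
        raise ValueError(f"unknown hierarchy level {level!r}")
    if len(table) == 0 or col not in table.columns:
        return pd.DataFrame(columns=[col, "count"])
    counts = table[col].value_counts()
    df = counts.rename_axis(col).reset_index(name="count")
    return df.sort_values(["count", col], ascending=[False, True], ignore_index=True)


def annotate_selection(
    selection: GroupSelection, affine: np.ndarray, atlas: AtlasTable
) -> pd.DataFrame:
    """Backtrack S to MNI, convert to Talairach and attach region labels."""
    from .fusion import backtrack_coordinates

    return label_coordinates(backtrack_coordinates(selection, affine), atlas)
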