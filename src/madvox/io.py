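"""Reading and writing neuroimaging volumes, cohort manifests and masks.

This module owns every coordinate-convention decision in the package:
voxel indices are 0-based integer triples in (x, y, z) order, world
coordinates are RAS+ millimetres obtained through the image affine, and
the time axis is always last, so a scan array has shape (x, y, z, t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("G1", "G2")

MANIFEST_COLUMNS = ("path", "subject_id", "group", "run_id")


class GridMismatchError(ValueError):
    """Scans or masks in one analysis do not share a spatial grid."""


@dataclass
class SubjectScan:
    """One subject-run 4D acquisition.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities; each spatial position carries a time series
        ("fiber") along the last axis.
    affine : ndarray, shape (4, 4)
        Voxel-to-world matrix in mm (RAS+).
    tr_seconds : float
        Repetition time between successive volumes.
    subject_id, group, run_id : str
        Cohort identifiers; ``group`` must be one of ``G1``/``G2``.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str
    group: str
    run_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"scan data must be 4D (x, y, z, t); got {self.data.ndim} axes"
            )
        if self.data.shape[3] < 2:
            raise ValueError("scan needs at least 2 timepoints")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean 3D in-brain mask on the same grid as the scans it masks."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("brain mask must be 3D")


@dataclass
class CohortManifest:
    """Cohort table: one row per subject-run with file path and labels."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        bad = set(self.rows["group"]) - set(GROUPS)
        if bad:
            raise ValueError(
                f"manifest group labels must be in {GROUPS}; found {sorted(bad)}"
            )
        per_subject = self.rows.groupby("subject_id")["group"].nunique()
        if (per_subject > 1).any():
            dup = per_subject[per_subject > 1].index.tolist()
            raise ValueError(f"subjects mapped to more than one group: {dup}")

    @property
    def m_per_group(self) -> dict[str, int]:
        return (
            self.rows.drop_duplicates("subject_id")
            .groupby("group")["subject_id"]
            .count()
            .to_dict()
        )

    def subjects(self, group: str | None = None) -> list[str]:
        rows = self.rows if group is None else self.rows[self.rows["group"] == group]
        return sorted(rows["subject_id"].unique())


def load_manifest(path: str | Path, group_aliases: dict[str, str] | None = None) -> CohortManifest:
    """Read a cohort manifest CSV (`path,subject_id,group,run_id` header).

    ``group_aliases`` optionally maps raw group strings onto G1/G2.
    """
    rows = pd.read_csv(path, dtype=str)
    if group_aliases:
        rows["group"] = rows["group"].map(lambda g: group_aliases.get(g, g))
    return CohortManifest(rows)


def load_scan(
    path: str | Path,
    subject_id: str = "",
    group: str = "G1",
    run_id: str = "",
    tr_override: float | None = None,
) -> SubjectScan:
    """Load a 4D NIfTI-1 volume as a :class:`SubjectScan`.

    TR is taken from the header's time-axis zoom; a manifest-supplied
    ``tr_override`` wins over the header (shared-data headers are often
    wrong).
    """
    try:
        img = nib.load(str(path))
        shape = img.shape
    except Exception as exc:  # nibabel raises several format error types
        raise ValueError(f"cannot read NIfTI image {path}: {exc}") from exc
    if len(shape) != 4:
        raise ValueError(f"expected a 4D image, got {len(shape)}D: {path}")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    tr = float(tr_override) if tr_override is not None else float(zooms[3])
    if tr <= 0:
        tr = 1.0  # headers with unset TR store 0; fall back to a unit TR
    return SubjectScan(
        data=data,
        affine=np.asarray(img.affine, dtype=float),
        tr_seconds=tr,
        subject_id=subject_id,
        group=group,
        run_id=run_id,
    )


def load_cohort(manifest: CohortManifest, base_dir: str | Path | None = None) -> list[SubjectScan]:
    """Load every scan listed in a manifest; all must share one grid."""
    scans = []
    for row in manifest.rows.itertuples(index=False):
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        tr = getattr(row, "tr_seconds", None)
        scans.append(
            load_scan(
                p,
                subject_id=row.subject_id,
                group=row.group,
                run_id=row.run_id,
                tr_override=float(tr) if tr not in (None, "") and not pd.isna(tr) else None,
            )
        )
    check_shared_grid(scans)
    return scans


def check_shared_grid(scans: list[SubjectScan]) -> tuple[int, int, int]:
    grids = {s.grid for s in scans}
    if len(grids) > 1:
        raise GridMismatchError(
            f"all scans in one analysis must share a grid; found {sorted(grids)}"
        )
    return next(iter(grids))


def save_scan(scan: SubjectScan, path: str | Path) -> None:
    """Write a scan as NIfTI-1 with TR stored in the time-axis zoom."""
    img = nib.Nifti1Image(np.asarray(scan.data, dtype=np.float32), scan.affine)
    zooms = img.header.get_zooms()
    img.header.set_zooms(zooms[:3] + (scan.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def n_voxels(scan_or_grid: SubjectScan | tuple[int, int, int]) -> int:
    """Number of voxels in the spatial grid (product of x, y, z extents)."""
    grid = scan_or_grid.grid if isinstance(scan_or_grid, SubjectScan) else tuple(scan_or_grid)
    if len(grid) != 3:
        raise ValueError("grid must have exactly three spatial dimensions")
    return int(np.prod([int(g) for g in grid]))


def n_volumes(duration_seconds: float, tr_seconds: float) -> int:
    """Number of whole-brain volumes acquired in ``duration_seconds`` at one per TR."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return int(round(duration_seconds / tr_seconds))


def voxel_to_world(index, affine: np.ndarray, grid: tuple[int, int, int] | None = None) -> np.ndarray:
    """Map a 0-based voxel index triple to world mm via ``affine @ (i, j, k, 1)``."""
    idx = np.asarray(index, dtype=float)
    if grid is not None:
        ii = np.atleast_2d(idx)
        if (ii < 0).any() or (ii >= np.asarray(grid)).any():
            raise IndexError(f"voxel index {index} out of bounds for grid {grid}")
    return nib.affines.apply_affine(np.asarray(affine, dtype=float), idx)


def world_to_voxel(world, affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; rounds to the nearest grid point."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    out = nib.affines.apply_affine(inv, np.asarray(world, dtype=float))
    return np.rint(out).astype(int)


def compute_brain_mask(scan: SubjectScan, fraction: float = 0.1) -> BrainMask:
    """Threshold the temporal-mean image to separate head from background.

    A voxel is in-brain when its temporal mean exceeds ``fraction`` times
    the global mean of temporal means. An all-zero scan yields an empty
    mask and a warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    tmean = scan.data.mean(axis=3)
    global_mean = float(tmean.mean())
    if global_mean == 0.0:
        warnings.warn("all-zero scan: brain mask is empty", stacklevel=2)
        return BrainMask(np.zeros(scan.grid, dtype=bool), scan.affine)
    return BrainMask(tmean > fraction * global_mean, scan.affine)


def write_selection_nifti(selected: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a boolean 3D selection as a 0/1 NIfTI-1 volume."""
    vol = np.asarray(selected, dtype=np.uint8)
    if vol.ndim != 3:
        raise ValueError("selection volume must be 3D")
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, dtype=float)), str(path))


def read_selection_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0
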