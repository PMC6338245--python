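"""Per-voxel mean-deviation statistics and per-subject voxel selection.

The activation statistic is model-free: for each voxel's time series
``V_i = [v_i1 .. v_in]`` compute the absolute deviations from the
temporal mean, ``d_ij = |v_ij - mu_i|``, and their median ``M_i``. A
voxel counts as highly activated for a subject when its deviation
exceeds ``alpha * M_i`` at any timepoint, i.e. ``max_j d_ij > alpha *
M_i``. The threshold scale ``M_i`` adapts per voxel, so the criterion is
invariant to affine intensity changes and needs no task timing or
haemodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BrainMask, SubjectScan

#: Eligibility floor on the median deviation. A voxel whose median
#: deviation is (numerically) zero — e.g. background where most samples
#: equal the mean exactly — would pass any multiplicative threshold
#: vacuously on a single nonzero blip; such voxels are never selected.
DEFAULT_ELIGIBILITY_FLOOR = 1e-12

RUN_COMBINE_MODES = ("union", "intersection", "pooled")


@dataclass
class DeviationProfile:
    """Per-voxel temporal summary statistics on one spatial grid.

    ``mu`` is the temporal mean, ``dev_max`` the maximum absolute
    deviation from it, and ``median_dev`` the median absolute deviation
    (even-length median = midpoint of the two central order statistics).
    """

    mu: np.ndarray
    dev_max: np.ndarray
    median_dev: np.ndarray
    subject_id: str = ""
    group: str = ""
    run_ids: tuple[str, ...] = ()

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.mu.shape


@dataclass
class SelectionMask:
    """Boolean volume of selected voxels with selection provenance."""

    selected: np.ndarray
    alpha: float
    subject_id: str = ""
    group: str = ""
    run_ids: tuple[str, ...] = ()
    combine_mode: str = "single_run"

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.selected.shape

    @property
    def count(self) -> int:
        return int(self.selected.sum())

    def indices(self) -> list[tuple[int, int, int]]:
        """Selected voxel indices as a lexicographically sorted list."""
        return [tuple(int(v) for v in ijk) for ijk in np.argwhere(self.selected)]


def deviation_profile(scan: SubjectScan, mask: BrainMask | None = None) -> DeviationProfile:
    """Temporal mean, max |deviation| and median |deviation| per voxel.

    Voxels outside ``mask`` (if given) get all three statistics set to 0,
    which renders them ineligible for selection.
    """
    if scan.n_timepoints < 2:
        raise ValueError("deviation profile needs at least 2 timepoints")
    data = np.asarray(scan.data, dtype=np.float64)
    mu = data.mean(axis=3)
    dev = np.abs(data - mu[..., None])
    profile = DeviationProfile(
        mu=mu,
        dev_max=dev.max(axis=3),
        median_dev=np.median(dev, axis=3),
        subject_id=scan.subject_id,
        group=scan.group,
        run_ids=(scan.run_id,),
    )
    if mask is not None:
        if mask.mask.shape != profile.grid:
            raise ValueError("brain mask grid does not match scan grid")
        out = ~mask.mask
        for arr in (profile.mu, profile.dev_max, profile.median_dev):
            arr[out] = 0.0
    return profile


def select_voxels(
    profile: DeviationProfile,
    alpha: float,
    eligibility_floor: float = DEFAULT_ELIGIBILITY_FLOOR,
) -> SelectionMask:
    """Select voxels whose peak deviation strictly exceeds ``alpha * M``.

    The comparison is strict (a tie at exactly ``alpha * M`` is not
    selected) and only voxels with ``median_dev > eligibility_floor``
    are eligible, so constant and zero-median-deviation series are
    never selected.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    selected = (profile.median_dev > eligibility_floor) & (
        profile.dev_max > alpha * profile.median_dev
    )
    mode = "single_run" if len(profile.run_ids) <= 1 else "pooled"
    return SelectionMask(
        selected=selected,
        alpha=float(alpha),
        subject_id=profile.subject_id,
        group=profile.group,
        run_ids=profile.run_ids,
        combine_mode=mode,
    )


def combine_runs(masks: list[SelectionMask], mode: str = "union") -> SelectionMask:
    """Merge one subject's per-run selections by set union or intersection."""
    if not masks:
        raise ValueError("no selection masks to combine")
    if mode not in ("union", "intersection"):
        raise ValueError(f"combine mode must be union or intersection, got {mode!r}")
    subjects = {m.subject_id for m in masks}
    alphas = {m.alpha for m in masks}
    grids = {m.grid for m in masks}
    if len(subjects) > 1:
        raise ValueError(f"cannot combine runs across subjects: {sorted(subjects)}")
    if len(alphas) > 1:
        raise ValueError(f"cannot combine runs with mixed alphas: {sorted(alphas)}")
    if len(grids) > 1:
        raise ValueError("cannot combine runs on different grids")
    stack = np.stack([m.selected for m in masks])
    combined = stack.all(axis=0) if mode == "intersection" else stack.any(axis=0)
    run_ids = tuple(r for m in masks for r in m.run_ids)
    return SelectionMask(
        selected=combined,
        alpha=masks[0].alpha,
        subject_id=masks[0].subject_id,
        group=masks[0].group,
        run_ids=run_ids,
        combine_mode=mode,
    )


def pool_runs(scans: list[SubjectScan]) -> SubjectScan:
    """Concatenate one subject's runs along time into a single long series."""
    if not scans:
        raise ValueError("no scans to pool")
    if len({s.subject_id for s in scans}) > 1:
        raise ValueError("cannot pool runs across subjects")
    if len({s.grid for s in scans}) > 1:
        raise ValueError("cannot pool runs on different grids")
    ordered = sorted(scans, key=lambda s: s.run_id)
    return SubjectScan(
        data=np.concatenate([s.data for s in ordered], axis=3),
        affine=ordered[0].affine,
        tr_seconds=ordered[0].tr_seconds,
        subject_id=ordered[0].subject_id,
        group=ordered[0].group,
        run_id="+".join(s.run_id for s in ordered),
    )


def subject_selection(
    scans: list[SubjectScan],
    alpha: float,
    mask: BrainMask | None = None,
    run_combine: str = "union",
    eligibility_floor: float = DEFAULT_ELIGIBILITY_FLOOR,
) -> SelectionMask:
    """Phase-I selection for one subject across their runs.

    ``run_combine`` chooses how the runs enter: per-run selection merged
    by ``union`` (a voxel is kept if activated in any run; the default)
    or ``intersection``, or ``pooled`` (concatenate the runs into one
    long series and select once).
    """
    if run_combine not in RUN_COMBINE_MODES:
        raise ValueError(f"run_combine must be one of {RUN_COMBINE_MODES}")
    if run_combine == "pooled":
        pooled = pool_runs(scans)
        profile = deviation_profile(pooled, mask)
        profile.run_ids = tuple(s.run_id for s in scans)
        return select_voxels(profile, alpha, eligibility_floor)
    per_run = [
        select_voxels(deviation_profile(s, mask), alpha, eligibility_floor) for s in scans
    ]
    if len(per_run) == 1:
        return per_run[0]
    return combine_runs(per_run, mode=run_combine)


def cohort_subject_masks(
    scans: list[SubjectScan],
    alpha: float,
    mask: BrainMask | None = None,
    run_combine: str = "union",
    eligibility_floor: float = DEFAULT_ELIGIBILITY_FLOOR,
) -> dict[str, SelectionMask]:
    """Per-subject selection masks for a whole cohort, keyed by subject id."""
    by_subject: dict[str, list[SubjectScan]] = {}
    for s in scans:
        by_subject.setdefault(s.subject_id, []).append(s)
    return {
        sid: subject_selection(runs, alpha, mask, run_combine, eligibility_floor)
        for sid, runs in sorted(by_subject.items())
    }


def alpha_sweep(
    scans: list[SubjectScan],
    alphas: list[float],
    consensus: float = 1.0,
    mask: BrainMask | None = None,
    run_combine: str = "union",
) -> pd.DataFrame:
    """Final union-set size |S| for each threshold multiplier alpha.

    Runs the full two-phase pipeline per alpha. Deviation profiles do
    not depend on alpha, so they are computed once and re-thresholded,
    which keeps a 7-point sweep close to the cost of a single run.
    ``|S|`` is non-increasing in alpha by construction.
    """
    from .fusion import fuse_cohort  # local import to avoid a cycle

    if not scans:
        raise ValueError("empty cohort")
    alphas = [float(a) for a in alphas]
    if alphas != sorted(alphas):
        raise ValueError("alphas must be sorted ascending")

    if run_combine == "pooled":
        by_subject: dict[str, list[SubjectScan]] = {}
        for s in scans:
            by_subject.setdefault(s.subject_id, []).append(s)
        profiles = {
            sid: [deviation_profile(pool_runs(runs), mask)]
            for sid, runs in sorted(by_subject.items())
        }
        merge = "union"  # single pooled profile per subject; merge is a no-op
    else:
        profiles = {}
        for s in scans:
            profiles.setdefault(s.subject_id, []).append(deviation_profile(s, mask))
        merge = run_combine

    groups = {s.subject_id: s.group for s in scans}
    rows = []
    for alpha in alphas:
        subject_masks = {}
        for sid, profs in profiles.items():
            per_run = [select_voxels(p, alpha) for p in profs]
            subject_masks[sid] = per_run[0] if len(per_run) == 1 else combine_runs(per_run, merge)
        sel = fuse_cohort(subject_masks, groups, consensus=consensus)
        rows.append({"alpha": alpha, "union_size": len(sel.union_set)})
    return pd.DataFrame(rows)
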