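"""Synthetic multi-subject, multi-run 4D cohorts with known ground truth.

The generator emulates the shape of a task-fMRI cohort at desk scale:
two groups of subjects, several runs each, every run a 4D array of
baseline + noise in which a sparse set of "active" voxels additionally
carries short boxcar transients. Implanted transients are sized so the
selection inequality ``dev_max > alpha * median_dev`` holds with margin
(the generator asserts this after the fact), giving exact ground truth
for sensitivity/specificity accounting.

Activation layout
-----------------
Every subject activates the union of the two group-common voxel sets at
the base amplitude; on top of that, subjects receive an extra
``group_effect`` of amplitude at their *own* group's common set. The
group difference is therefore purely one of response magnitude at fixed
locations: with ``group_effect = 0`` the two groups are statistically
identical (classification must fall to chance), while the default
effect separates them cleanly. Each subject also gets a few
idiosyncratic active voxels (rate ``subject_extra_rate``), so the
per-subject selections within a group overlap only partially; the
group-wise intersection strips these extras, because they essentially
never coincide across all subjects.

Noise
-----
Default noise is i.i.d. uniform on ``[-√3·sd, +√3·sd]`` (variance
matched to ``noise_sd``). Bounded noise gives the deviation statistic a
hard ceiling — max |deviation| / median |deviation| < 2 for a pure-noise
series — so background voxels are *never* selected at the default
threshold α = 3, making false-positive accounting exact. Gaussian noise
(``noise="gaussian"``) is available for realism but has unbounded
max/median ratio: over 140 timepoints nearly every white-Gaussian voxel
exceeds 3 × median, so it is unsuitable for ground-truth recovery work.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .io import SubjectScan

VoxelIndex = tuple[int, int, int]


@dataclass
class SyntheticSpec:
    """Cohort-generation parameters (defaults = the desk-scale study)."""

    grid: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 140
    tr_seconds: float = 2.0
    m_per_group: int = 6
    runs_per_subject: int = 2
    baseline: float = 100.0
    noise_sd: float = 2.0
    active_common_g1: list[VoxelIndex] | None = None  # None -> default cluster
    active_common_g2: list[VoxelIndex] | None = None
    spike_amplitude: float = 40.0
    spike_width_timepoints: int = 3
    group_effect: float = 15.0
    subject_extra_rate: float = 0.001
    noise: str = "uniform"  # or "gaussian"
    hrf: bool = False
    alpha_margin_check: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(g) for g in self.grid)
        if self.active_common_g1 is None:
            self.active_common_g1 = _default_cluster(self.grid, offset=2)
        if self.active_common_g2 is None:
            self.active_common_g2 = _default_cluster(self.grid, offset=3)
        self.active_common_g1 = sorted(tuple(int(c) for c in v) for v in self.active_common_g1)
        self.active_common_g2 = sorted(tuple(int(c) for c in v) for v in self.active_common_g2)
        for v in self.active_common_g1 + self.active_common_g2:
            if any(c < 0 or c >= g for c, g in zip(v, self.grid)):
                raise ValueError(f"active voxel {v} outside grid {self.grid}")
        if self.noise not in ("uniform", "gaussian"):
            raise ValueError("noise must be 'uniform' or 'gaussian'")
        if not 0 < self.spike_width_timepoints < self.n_timepoints:
            raise ValueError("spike width must lie in (0, n_timepoints)")

    @property
    def active_union(self) -> list[VoxelIndex]:
        return sorted(set(self.active_common_g1) | set(self.active_common_g2))


def _default_cluster(grid: tuple[int, int, int], offset: int) -> list[VoxelIndex]:
    """A 3×3×3 block starting at (offset, offset, offset), clipped to grid."""
    return [
        (i, j, k)
        for i in range(offset, min(offset + 3, grid[0]))
        for j in range(offset, min(offset + 3, grid[1]))
        for k in range(offset, min(offset + 3, grid[2]))
    ]


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default recovery cohort: 12³ grid, 140 timepoints, 6+6 subjects, 2 runs."""
    return SyntheticSpec(seed=seed, **overrides)


def classification_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Group-differential cohort sized for stratified 10-fold CV.

    17 subjects per group (half the reference cohort's 34), one run, a
    10³ grid; everything else as the default spec.
    """
    overrides.setdefault("grid", (10, 10, 10))
    overrides.setdefault("m_per_group", 17)
    overrides.setdefault("runs_per_subject", 1)
    return SyntheticSpec(seed=seed, **overrides)


def _double_gamma_hrf(n: int, tr: float) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalized."""
    t = np.arange(n) * tr
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def _transient(spec: SyntheticSpec, onset: int, amplitude: float) -> np.ndarray:
    """Additive transient time course for one active voxel."""
    course = np.zeros(spec.n_timepoints)
    course[onset : onset + spec.spike_width_timepoints] = 1.0
    if spec.hrf:
        kernel = _double_gamma_hrf(min(spec.n_timepoints, 32), spec.tr_seconds)
        course = np.convolve(course, kernel)[: spec.n_timepoints]
        course /= course.max()
    return amplitude * course


class AmplitudeMarginError(AssertionError):
    """Implanted transients too small to guarantee selection at alpha."""


def generate_cohort(spec: SyntheticSpec) -> tuple[list[SubjectScan], dict]:
    """Generate all subject-run scans plus a ground-truth record.

    Returns ``(scans, truth)`` where ``truth`` holds the group-common
    sets, their union (the set the pipeline should recover as S) and the
    exact per-subject active sets (union + idiosyncratic extras). Fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -3.0 * (np.array(spec.grid) - 1) / 2.0  # grid centred on origin

    union = spec.active_union
    union_arr = set(union)
    scans: list[SubjectScan] = []
    per_subject_truth: dict[str, list[VoxelIndex]] = {}

    for group, own_set in (("G1", set(spec.active_common_g1)), ("G2", set(spec.active_common_g2))):
        for s in range(spec.m_per_group):
            sid = f"{group}_s{s:02d}"
            extras = _draw_extras(rng, spec, exclude=union_arr)
            active = sorted(union_arr | extras)
            per_subject_truth[sid] = active
            for r in range(spec.runs_per_subject):
                data = _noise_volume(rng, spec)
                for v in active:
                    amp = spec.spike_amplitude + (spec.group_effect if v in own_set else 0.0)
                    onset = int(rng.integers(0, spec.n_timepoints - spec.spike_width_timepoints + 1))
                    data[v] += _transient(spec, onset, amp)
                scan = SubjectScan(
                    data=data,
                    affine=affine,
                    tr_seconds=spec.tr_seconds,
                    subject_id=sid,
                    group=group,
                    run_id=f"run{r + 1}",
                )
                _assert_selection_margin(scan, active, spec)
                scans.append(scan)

    truth = {
        "g1_common": spec.active_common_g1,
        "g2_common": spec.active_common_g2,
        "union": union,
        "per_subject": per_subject_truth,
        "grid": spec.grid,
    }
    return scans, truth


def _noise_volume(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    shape = spec.grid + (spec.n_timepoints,)
    if spec.noise == "uniform":
        half_width = np.sqrt(3.0) * spec.noise_sd
        noise = rng.uniform(-half_width, half_width, size=shape)
    else:
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
    return spec.baseline + noise


def _draw_extras(
    rng: np.random.Generator, spec: SyntheticSpec, exclude: set[VoxelIndex]
) -> set[VoxelIndex]:
    hits = np.argwhere(rng.random(spec.grid) < spec.subject_extra_rate)
    return {tuple(int(c) for c in v) for v in hits} - exclude


def _assert_selection_margin(scan: SubjectScan, active: list[VoxelIndex], spec: SyntheticSpec) -> None:
    """Every implanted voxel must clear alpha × median deviation with margin."""
    if not active:
        return
    cols = tuple(np.array(active).T)
    fibers = scan.data[cols]  # n_active × t
    mu = fibers.mean(axis=1, keepdims=True)
    dev = np.abs(fibers - mu)
    dev_max = dev.max(axis=1)
    med = np.median(dev, axis=1)
    ratio = dev_max / np.maximum(med, 1e-300)
    margin = 1.2
    if not np.all(ratio > margin * spec.alpha_margin_check):
        worst = float(ratio.min())
        raise AmplitudeMarginError(
            f"implanted transient too weak: min dev_max/median_dev = {worst:.2f} "
            f"<= {margin:.1f} × alpha ({spec.alpha_margin_check}). Increase "
            "spike_amplitude or spike_width_timepoints, or lower noise_sd."
        )


@dataclass
class RecoveryMetrics:
    """Exact selection-recovery accounting against a ground-truth set."""

    sensitivity: float | None
    specificity: float
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.true_positives,
            "fp": self.false_positives,
            "fn": self.false_negatives,
            "tn": self.true_negatives,
        }


def evaluate_recovery(
    selected: list[VoxelIndex],
    truth_set: list[VoxelIndex],
    grid: tuple[int, int, int],
) -> RecoveryMetrics:
    """Sensitivity/specificity of a selected set against ground truth.

    Counts are exact integers; the rates are exact rationals reported as
    floats. An empty truth set leaves sensitivity undefined (None).
    """
    sel = {tuple(int(c) for c in v) for v in selected}
    true = {tuple(int(c) for c in v) for v in truth_set}
    n_total = int(np.prod(grid))
    tp = len(sel & true)
    fp = len(sel - true)
    fn = len(true - sel)
    tn = n_total - tp - fp - fn
    sensitivity = float(Fraction(tp, len(true))) if true else None
    negatives = n_total - len(true)
    specificity = float(Fraction(tn, negatives)) if negatives else 1.0
    return RecoveryMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        true_negatives=tn,
    )
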