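import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from madvox import io, select
from madvox.select import (
    alpha_sweep,
    combine_runs,
    deviation_profile,
    pool_runs,
    select_voxels,
    subject_selection,
)
from madvox.simulate import SyntheticSpec, generate_cohort

from conftest import make_scan, make_volume_scan


def literal_selection(data, alpha):
    """Triple-loop reference implementation of the selection rule.

    For each voxel: absolute deviations from the temporal mean, their
    median, and selection when the peak deviation strictly exceeds
    alpha times the median (median must be positive to be eligible).
    """
    import statistics

    nx, ny, nz, nt = data.shape
    out = np.zeros((nx, ny, nz), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                series = [float(data[i, j, k, t]) for t in range(nt)]
                mu = sum(series) / nt
                devs = [abs(v - mu) for v in series]
                m = statistics.median(devs)
                out[i, j, k] = m > 1e-12 and max(devs) > alpha * m
    return out


class TestDeviationProfile:
    @pytest.mark.parametrize(
        "series,mu,dev_max,median_dev",
        [
            ([5, 5, 5, 5], 5.0, 0.0, 0.0),
            ([10, 10, 10, 10, 10, 10, 10, 50], 15.0, 35.0, 5.0),
            ([1, 2, 1, 2, 1, 2, 1, 2], 1.5, 0.5, 0.5),
        ],
    )
    def test_hand_computed_statistics(self, series, mu, dev_max, median_dev):
        p = deviation_profile(make_scan(series))
        assert p.mu[0, 0, 0] == pytest.approx(mu)
        assert p.dev_max[0, 0, 0] == pytest.approx(dev_max)
        assert p.median_dev[0, 0, 0] == pytest.approx(median_dev)

    def test_even_length_median_is_midpoint_of_central_order_stats(self):
        # deviations from mu=2.5 are [1.5, 0.5, 0.5, 1.5]; median = 1.0
        p = deviation_profile(make_scan([1, 2, 3, 4]))
        assert p.median_dev[0, 0, 0] == pytest.approx(1.0)

    def test_masked_voxels_zeroed(self):
        data = np.ones((2, 2, 2, 6))
        data[0, 0, 0] = [10, 10, 10, 10, 10, 50]
        scan = make_volume_scan(data)
        mask = io.BrainMask(np.zeros((2, 2, 2), dtype=bool), np.eye(4))
        p = deviation_profile(scan, mask)
        assert p.mu.max() == 0 and p.dev_max.max() == 0 and p.median_dev.max() == 0


class TestSelectVoxels:
    def test_spike_series_selected_at_alpha_3(self):
        p = deviation_profile(make_scan([10, 10, 10, 10, 10, 10, 10, 50]))
        assert select_voxels(p, 3.0).selected[0, 0, 0]  # 35 > 3*5

    def test_oscillating_series_not_selected(self):
        p = deviation_profile(make_scan([1, 2, 1, 2, 1, 2, 1, 2]))
        assert not select_voxels(p, 3.0).selected[0, 0, 0]  # 0.5 < 1.5

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 3.0, 100.0])
    def test_constant_series_never_selected(self, alpha):
        p = deviation_profile(make_scan([5.0] * 8))
        assert not select_voxels(p, alpha).selected.any()

    def test_zero_median_deviation_series_ineligible(self):
        # mean 0, deviations [0,0,0,0,0,0,3,3]: median 0, peak 3 — without
        # the eligibility floor any alpha would select this vacuously
        p = deviation_profile(make_scan([0.0] * 6 + [3.0, -3.0]))
        assert p.median_dev[0, 0, 0] == 0.0
        assert p.dev_max[0, 0, 0] == pytest.approx(3.0)
        assert not select_voxels(p, 3.0).selected.any()

    def test_threshold_is_strict(self):
        # dev_max = 3, median_dev = 1: at alpha=3 the tie must NOT select
        p = deviation_profile(make_scan([-1, 1, -1, 1, -3, 3, -1, 1]))
        assert p.dev_max[0, 0, 0] == pytest.approx(3.0)
        assert p.median_dev[0, 0, 0] == pytest.approx(1.0)
        assert not select_voxels(p, 3.0).selected.any()
        assert select_voxels(p, 2.999).selected.any()

    def test_nonpositive_alpha_rejected(self):
        p = deviation_profile(make_scan([1, 2, 3, 4]))
        with pytest.raises(ValueError, match="alpha"):
            select_voxels(p, 0.0)


class TestSelectionOracle:
    def test_vectorized_matches_literal_loop_on_random_scans(self, rng):
        for _ in range(5):
            data = rng.normal(50, 10, size=(4, 4, 4, 12))
            scan = make_volume_scan(data)
            for alpha in (1.0, 3.0):
                got = select_voxels(deviation_profile(scan), alpha).selected
                np.testing.assert_array_equal(got, literal_selection(data, alpha))


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 0.01),
        c=st.floats(-100, 100),
    )
    def test_affine_intensity_invariance(self, seed, a, c):
        data = np.random.default_rng(seed).normal(0, 1, size=(3, 3, 3, 10))
        base = select_voxels(deviation_profile(make_volume_scan(data)), 3.0).selected
        scaled = select_voxels(deviation_profile(make_volume_scan(a * data + c)), 3.0).selected
        np.testing.assert_array_equal(base, scaled)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_time_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, size=(3, 3, 3, 10))
        perm = rng.permutation(10)
        base = select_voxels(deviation_profile(make_volume_scan(data)), 3.0).selected
        shuf = select_voxels(deviation_profile(make_volume_scan(data[..., perm])), 3.0).selected
        np.testing.assert_array_equal(base, shuf)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lo=st.floats(0.5, 5), hi=st.floats(0.0, 5))
    def test_selection_monotone_in_alpha(self, seed, lo, hi):
        data = np.random.default_rng(seed).normal(0, 1, size=(3, 3, 3, 10))
        p = deviation_profile(make_volume_scan(data))
        smaller = select_voxels(p, lo).selected
        larger = select_voxels(p, lo + hi).selected
        assert np.all(smaller | ~larger)  # selected(alpha') subset of selected(alpha)


class TestCombineRuns:
    def _mask(self, voxels, subject="s0", alpha=3.0, run="r1"):
        sel = np.zeros((3, 3, 3), dtype=bool)
        for v in voxels:
            sel[v] = True
        return select.SelectionMask(sel, alpha=alpha, subject_id=subject, run_ids=(run,))

    def test_single_run_is_identity(self):
        m = self._mask([(0, 0, 0)])
        for mode in ("union", "intersection"):
            np.testing.assert_array_equal(combine_runs([m], mode).selected, m.selected)

    def test_union_and_intersection_set_algebra(self):
        a = (0, 0, 0)
        b = (1, 1, 1)
        m1 = self._mask([a])
        m2 = self._mask([a, b], run="r2")
        assert combine_runs([m1, m2], "union").indices() == [a, b]
        assert combine_runs([m1, m2], "intersection").indices() == [a]

    def test_union_bounds_each_run_bounds_intersection(self, rng):
        masks = [
            select.SelectionMask(rng.random((4, 4, 4)) < 0.3, 3.0, subject_id="s0",
                                 run_ids=(f"r{i}",))
            for i in range(4)
        ]
        union = combine_runs(masks, "union").count
        inter = combine_runs(masks, "intersection").count
        for m in masks:
            assert inter <= m.count <= union

    def test_mixed_subjects_or_alphas_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            combine_runs([self._mask([]), self._mask([], subject="s1")])
        with pytest.raises(ValueError, match="alphas"):
            combine_runs([self._mask([]), self._mask([], alpha=4.0)])


class TestRunHandling:
    def test_pooled_runs_concatenate_time_axis(self):
        r1 = make_scan([1, 2, 3, 4], run_id="r1")
        r2 = make_scan([5, 6, 7, 8], run_id="r2")
        pooled = pool_runs([r1, r2])
        assert pooled.n_timepoints == 8
        np.testing.assert_array_equal(pooled.data[0, 0, 0], np.arange(1, 9))

    def test_subject_selection_modes_agree_on_single_run(self):
        scan = make_scan([10, 10, 10, 10, 10, 10, 10, 50])
        for mode in ("union", "intersection", "pooled"):
            assert subject_selection([scan], 3.0, run_combine=mode).selected[0, 0, 0]


class TestAlphaSweep:
    def test_sizes_non_increasing_and_vanish_at_large_alpha(self):
        spec = SyntheticSpec(grid=(8, 8, 8), n_timepoints=40, m_per_group=2,
                             runs_per_subject=2, seed=3)
        scans, _ = generate_cohort(spec)
        table = alpha_sweep(scans, [1, 2, 3, 4, 5, 6, 7, 100])
        sizes = table["union_size"].to_numpy()
        assert np.all(np.diff(sizes) <= 0)
        assert sizes[-1] == 0

    def test_all_active_cohort_fully_selected_below_min_ratio(self):
        grid = (4, 4, 4)
        every = [(i, j, k) for i in range(4) for j in range(4) for k in range(4)]
        spec = SyntheticSpec(grid=grid, n_timepoints=40, m_per_group=2, runs_per_subject=1,
                             active_common_g1=every, active_common_g2=every,
                             subject_extra_rate=0.0, seed=4)
        scans, _ = generate_cohort(spec)
        table = alpha_sweep(scans, [3.0])
        assert table["union_size"].iloc[0] == io.n_voxels(grid)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_sweep([], [1.0])

    def test_unsorted_alphas_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            alpha_sweep([make_scan([1, 2, 3, 4])], [3.0, 1.0])
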