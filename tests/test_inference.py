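import numpy as np
import pytest

from teflow import (
    PairedDataset,
    PeakWindow,
    TEEstimate,
    TEQuery,
    TesumSpec,
    bootstrap_tesum,
    concat_datasets,
    conditional_tesum,
    detect_coupling,
    difference_tesum,
    longest_significant_run,
    null_threshold,
    significant_te,
    te_timecourse,
    tesum,
)
from teflow.inference import TETimeCourse
from conftest import lagged_dataset


def course_from_values(values, significants, tc=2.0, direction="fw"):
    ests = tuple(
        TEEstimate(v, TEQuery(direction, tc, float(t)), 100, 0.01, s)
        for t, (v, s) in enumerate(zip(values, significants), start=int(tc) + 1)
    )
    return TETimeCourse(direction, tc, tc, ests)


class TestNullThreshold:
    def test_threshold_nonnegative(self):
        ds = lagged_dataset(100, coupling=0.0, seed=3)
        th = null_threshold(ds, TEQuery("fw", 2, 5), n_null=300, seed=0)
        assert th >= 0

    def test_tiny_dataset_rejected(self):
        ds = lagged_dataset(2, seed=0)
        with pytest.raises(ValueError):
            null_threshold(ds, TEQuery("fw", 2, 5), seed=0)

    def test_gaussian_null_alternative(self):
        ds = lagged_dataset(80, coupling=0.0, seed=3)
        th = null_threshold(ds, TEQuery("fw", 2, 5), n_null=100, seed=0, null_method="gaussian")
        assert th >= 0


class TestSignificantTE:
    def test_strong_coupling_flagged_significant(self):
        ds = lagged_dataset(400, coupling=1.5, seed=11)
        est = significant_te(ds, TEQuery("fw", 4, 5), seed=1)
        assert est.significant and est.value > est.threshold

    def test_uncoupled_not_flagged(self):
        ds = lagged_dataset(400, coupling=0.0, seed=11)
        est = significant_te(ds, TEQuery("fw", 4, 5), seed=1)
        assert not est.significant

    def test_deterministic_under_seed(self):
        ds = lagged_dataset(150, coupling=0.5, seed=5)
        a = significant_te(ds, TEQuery("fw", 4, 5), seed=42)
        b = significant_te(ds, TEQuery("fw", 4, 5), seed=42)
        assert a == b


class TestTimecourse:
    def test_single_entry_course(self):
        ds = lagged_dataset(100, coupling=1.0, seed=2)
        c = te_timecourse(ds, "fw", 4, t_values=[5.0], seed=0)
        assert len(c.estimates) == 1

    def test_empty_range_rejected(self):
        ds = lagged_dataset(100, seed=2)
        with pytest.raises(ValueError):
            te_timecourse(ds, "fw", 4, t_values=[], seed=0)

    def test_coupled_course_has_significant_block_at_lag(self):
        # one-step coupling: TE appears at t = tc + 1 only
        ds = lagged_dataset(500, coupling=1.5, seed=8)
        c = te_timecourse(ds, "fw", 4, seed=0)
        frame = c.as_frame()
        assert bool(frame.loc[frame.t == 5.0, "significant"].iloc[0])
        assert frame.loc[frame.t > 6.0, "significant"].mean() < 0.2

    def test_detection_rule_counts_consecutive_points(self):
        c = course_from_values([0.1] * 5, [True, True, True, False, True])
        assert longest_significant_run(c) == 3
        assert detect_coupling(c, min_run=3)
        assert not detect_coupling(c, min_run=4)


class TestTesum:
    def test_all_insignificant_gives_zero(self):
        c = course_from_values([0.1, 0.2, 0.3], [False] * 3)
        assert tesum(c, PeakWindow("w", "fw", 2, 3, 5)) == 0.0

    def test_sum_of_significant_entries(self):
        c = course_from_values([0.1, 0.2, 0.3], [True] * 3)
        assert tesum(c, PeakWindow("w", "fw", 2, 3, 5)) == pytest.approx(0.6)

    def test_additive_over_window_partition(self):
        c = course_from_values([0.1, 0.2, 0.3, 0.4], [True, False, True, True])
        whole = tesum(c, PeakWindow("w", "fw", 2, 3, 6))
        left = tesum(c, PeakWindow("l", "fw", 2, 3, 4))
        right = tesum(c, PeakWindow("r", "fw", 2, 5, 6))
        assert whole == pytest.approx(left + right)

    def test_monotone_in_window_length(self):
        c = course_from_values([0.1, 0.2, 0.3, 0.4], [True, True, False, True])
        sums = [tesum(c, PeakWindow("w", "fw", 2, 3, te)) for te in (3, 4, 5, 6)]
        assert all(a <= b for a, b in zip(sums, sums[1:]))

    def test_window_outside_course_rejected(self):
        c = course_from_values([0.1], [True])
        with pytest.raises(ValueError):
            tesum(c, PeakWindow("w", "fw", 2, 3, 99))

    def test_window_validation(self):
        with pytest.raises(ValueError):
            PeakWindow("w", "fw", 5, 4, 6)


class TestBootstrapTesum:
    window = PeakWindow("early", "fw", 4, 5, 7)

    def test_deterministic_under_seed_and_interval_order(self):
        ds = lagged_dataset(150, coupling=1.2, seed=3)
        a = bootstrap_tesum(ds, self.window, n_boot=15, n_null=150, seed=5)
        b = bootstrap_tesum(ds, self.window, n_boot=15, n_null=150, seed=5)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        assert a.lo <= a.mean <= a.hi

    def test_different_seeds_overlapping_intervals(self):
        ds = lagged_dataset(200, coupling=1.2, seed=3)
        a = bootstrap_tesum(ds, self.window, n_boot=20, n_null=200, seed=1)
        b = bootstrap_tesum(ds, self.window, n_boot=20, n_null=200, seed=2)
        assert not np.array_equal(a.replicates, b.replicates)
        assert a.lo < b.hi and b.lo < a.hi

    def test_stable_under_dataset_duplication(self):
        ds = lagged_dataset(150, coupling=1.5, seed=9)
        dup = concat_datasets([ds, ds, ds])
        a = bootstrap_tesum(ds, self.window, n_boot=30, n_null=300, seed=4)
        b = bootstrap_tesum(dup, self.window, n_boot=30, n_null=300, seed=4)
        assert b.mean == pytest.approx(a.mean, rel=0.25, abs=0.05)

    def test_full_data_threshold_mode(self):
        ds = lagged_dataset(150, coupling=1.2, seed=3)
        est = bootstrap_tesum(
            ds, self.window, n_boot=10, n_null=150, seed=5, recompute_threshold=False
        )
        assert est.mean > 0

    def test_replicate_count_matches_request(self):
        ds = lagged_dataset(120, coupling=1.0, seed=2)
        est = bootstrap_tesum(ds, self.window, n_boot=12, n_null=100, seed=0)
        assert est.replicates.shape == (12,)


class TestConditionalTesum:
    window = PeakWindow("early", "fw", 4, 5, 7)

    def test_single_group_rejected(self):
        ds = lagged_dataset(100, seed=0)
        with pytest.raises(ValueError):
            conditional_tesum([ds], self.window)

    def test_identical_groups_match_pooled(self):
        # two halves of one homogeneous population: conditioning is a no-op
        a = lagged_dataset(250, coupling=1.5, seed=21)
        b = lagged_dataset(250, coupling=1.5, seed=22)
        cond = conditional_tesum([a, b], self.window, n_boot=30, n_null=300, seed=1)
        pooled = bootstrap_tesum(concat_datasets([a, b]), self.window, n_boot=30, n_null=300, seed=1)
        assert cond.mean == pytest.approx(pooled.mean, rel=0.3, abs=0.05)

    def test_by_count_weighting_runs(self):
        a = lagged_dataset(120, coupling=1.0, seed=1)
        b = lagged_dataset(180, coupling=1.0, seed=2)
        est = conditional_tesum([a, b], self.window, weighting="by_count", n_boot=10, n_null=100, seed=0)
        assert est.n == 300


class TestDifferenceTesum:
    window = PeakWindow("early", "fw", 4, 5, 7)

    def test_self_difference_is_null(self):
        ds = lagged_dataset(150, coupling=1.2, seed=3)
        spec = TesumSpec((ds,), self.window)
        d = difference_tesum(spec, spec, n_boot=10, n_null=150, seed=7)
        assert d.mean_diff == 0.0
        assert not d.significant

    def test_antisymmetry_under_matched_seed(self):
        a = TesumSpec((lagged_dataset(150, coupling=1.5, seed=1),), self.window)
        b = TesumSpec((lagged_dataset(150, coupling=0.3, seed=2),), self.window)
        dab = difference_tesum(a, b, n_boot=12, n_null=150, seed=9)
        dba = difference_tesum(b, a, n_boot=12, n_null=150, seed=9)
        np.testing.assert_allclose(dab.replicates, -dba.replicates)

    def test_large_true_difference_is_significant_with_correct_sign(self):
        strong = TesumSpec((lagged_dataset(300, coupling=2.0, seed=5),), self.window)
        none = TesumSpec((lagged_dataset(300, coupling=0.0, seed=6),), self.window)
        d = difference_tesum(strong, none, n_boot=30, n_null=300, seed=3)
        assert d.significant and d.mean_diff > 0
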