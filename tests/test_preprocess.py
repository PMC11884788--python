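import numpy as np
import pytest

from teflow import ConditionMeta, TimeGrid
from teflow.preprocess import (
    IntensityTable,
    ResponseBinSpec,
    bin_by_causal_response,
    correct_bleedthrough,
    filter_low_intensity,
    normalize_and_baseline,
    normalize_intensities_to_max,
    remove_drift,
    response_intensity,
)
from conftest import lagged_dataset, trace


def intensity_table(tir, epi, times=None, channel="GFP"):
    tir = np.atleast_2d(np.asarray(tir, dtype=float))
    if times is None:
        times = np.arange(tir.shape[1], dtype=float) - 3.0
    grid = TimeGrid(np.asarray(times, dtype=float))
    epi = np.broadcast_to(np.asarray(epi, dtype=float), tir.shape).copy()
    ids = [f"c{i}" for i in range(tir.shape[0])]
    return IntensityTable(tir, epi, grid, ids, channel)


class TestBleedthrough:
    def test_zero_coefficients_identity(self):
        a = intensity_table([[10.0, 10.0, 10.0, 10.0]], 1.0)
        b = intensity_table([[4.0, 4.0, 4.0, 4.0]], 1.0, channel="TMR")
        ca, cb = correct_bleedthrough(a, b)
        np.testing.assert_array_equal(ca.tir, a.tir)
        np.testing.assert_array_equal(cb.tir, b.tir)

    def test_forced_arithmetic(self):
        a = intensity_table([[10.0] * 4], 1.0)
        b = intensity_table([[4.0] * 4], 1.0, channel="TMR")
        ca, _ = correct_bleedthrough(a, b, leak_b_into_a=0.25)
        assert ca.tir[0, 0] == pytest.approx(9.0)

    def test_nonphysical_coefficient_rejected(self):
        a = intensity_table([[1.0] * 4], 1.0)
        with pytest.raises(ValueError):
            correct_bleedthrough(a, a, leak_b_into_a=1.0)

    def test_clip_keeps_table_valid(self):
        a = intensity_table([[1.0] * 4], 1.0)
        b = intensity_table([[10.0] * 4], 1.0, channel="TMR")
        ca, _ = correct_bleedthrough(a, b, leak_b_into_a=0.5, clip=True)
        assert np.all(ca.tir == 0)


class TestRemoveDrift:
    grid = TimeGrid(np.arange(8.0) - 3.0)

    def test_zero_slope_unchanged(self):
        s = np.full(8, 2.0)
        np.testing.assert_allclose(remove_drift(s, self.grid), s)

    def test_linear_ramp_becomes_constant(self):
        a, b = 1.5, 0.3
        s = a + b * self.grid.times
        np.testing.assert_allclose(remove_drift(s, self.grid), np.full(8, a), atol=1e-12)

    def test_reference_subtract_self_gives_zero(self):
        s = np.arange(8.0)
        np.testing.assert_array_equal(
            remove_drift(s, self.grid, "reference_subtract", reference=s), np.zeros(8)
        )

    def test_insufficient_prestim_frames(self):
        g = TimeGrid(np.arange(5.0) - 1.0)  # one pre-stim frame
        with pytest.raises(ValueError):
            remove_drift(np.zeros(5), g)


class TestNormalizeAndBaseline:
    def test_forced_arithmetic(self):
        tir = [[0.11, 0.11, 0.11, 0.21]]
        table = intensity_table(tir, 1.0)
        resp = normalize_and_baseline(table)
        assert resp.values[0, -1] == pytest.approx(0.10, abs=1e-12)

    def test_tir_equal_epi_gives_zero(self):
        t = intensity_table(np.full((3, 6), 5.0), 5.0)
        resp = normalize_and_baseline(t)
        np.testing.assert_allclose(resp.values, 0.0, atol=1e-15)

    def test_baseline_is_three_frame_mean(self):
        tir = [[0.10, 0.12, 0.11, 0.50]]
        resp = normalize_and_baseline(intensity_table(tir, 1.0))
        assert resp.values[0, -1] == pytest.approx(0.50 - 0.11, abs=1e-12)

    def test_prestim_mean_zero_invariant(self, rng):
        tir = rng.uniform(0.5, 2.0, size=(20, 10))
        epi = rng.uniform(1.0, 3.0, size=(20, 10))
        g = TimeGrid(np.arange(10.0) - 3.0)
        resp = normalize_and_baseline(IntensityTable(tir, epi, g, [f"c{i}" for i in range(20)]))
        pre = resp.values[:, :3]
        np.testing.assert_allclose(pre.mean(axis=1), 0.0, atol=1e-14)

    def test_zero_epi_and_short_prestim_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_baseline(intensity_table([[1.0] * 6], 0.0))
        g = TimeGrid(np.arange(5.0) - 2.0)
        table = IntensityTable(np.ones((1, 5)), np.ones((1, 5)), g, ["c0"])
        with pytest.raises(ValueError):
            normalize_and_baseline(table)


class TestLowIntensityFilter:
    def test_counting(self):
        ds = lagged_dataset(10, seed=0)
        out, removed = filter_low_intensity(ds, np.arange(10.0), fraction=0.2)
        assert out.n_cells == 8
        assert removed == ("c0", "c1")

    def test_fraction_zero_identity(self):
        ds = lagged_dataset(5, seed=0)
        out, removed = filter_low_intensity(ds, np.ones(5), fraction=0.0)
        assert out.n_cells == 5 and removed == ()

    def test_ties_resolved_by_cell_order(self):
        ds = lagged_dataset(4, seed=0)
        out, removed = filter_low_intensity(ds, np.zeros(4), fraction=0.5)
        assert removed == ("c0", "c1")

    def test_never_removes_more_than_floor(self):
        for n in (7, 10, 13):
            ds = lagged_dataset(n, seed=n)
            out, removed = filter_low_intensity(ds, np.arange(float(n)), 0.2)
            assert len(removed) == int(np.floor(0.2 * n))

    def test_high_fraction_keeps_at_least_one_cell(self):
        # floor(0.99 * 3) = 2 removed; fraction >= 1 is rejected outright
        ds = lagged_dataset(3, seed=0)
        out, removed = filter_low_intensity(ds, np.arange(3.0), fraction=0.99)
        assert out.n_cells == 1
        with pytest.raises(ValueError):
            filter_low_intensity(ds, np.arange(3.0), fraction=1.0)


class TestResponseIntensity:
    def test_counting_61_frames(self):
        tm = trace(np.ones((2, 64)), times=np.arange(64.0) - 3.0)
        np.testing.assert_array_equal(response_intensity(tm, (0, 60)), [61.0, 61.0])

    def test_zero_trace(self):
        tm = trace(np.zeros((1, 10)))
        assert response_intensity(tm, (0, 9))[0] == 0.0

    def test_single_point_window(self):
        tm = trace([np.arange(10.0)])
        assert response_intensity(tm, (5, 5))[0] == 5.0

    def test_additive_over_disjoint_windows(self, rng):
        tm = trace(rng.standard_normal((4, 12)))
        total = response_intensity(tm, (0, 11))
        left = response_intensity(tm, (0, 5))
        right = response_intensity(tm, (6, 11))
        np.testing.assert_allclose(total, left + right, atol=1e-12)

    def test_empty_window_rejected(self):
        tm = trace(np.ones((1, 5)))
        with pytest.raises(ValueError):
            response_intensity(tm, (4, 2))

    def test_normalize_to_max_condition_mean(self):
        out = normalize_intensities_to_max({"lo": np.array([1.0, 3.0]), "hi": np.array([4.0, 4.0])})
        np.testing.assert_allclose(out["hi"], [1.0, 1.0])
        np.testing.assert_allclose(out["lo"], [0.25, 0.75])


class TestCausalResponseBinning:
    def make(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        ds = lagged_dataset(n, seed=seed)
        vals = ds.cause.values.copy()
        vals[:, ds.grid.index_of(5.0)] = rng.uniform(0, 1, n)
        return type(ds)(trace(vals, ds.grid.times, "cause", ds.cell_ids), ds.result, ds.condition)

    def test_uniform_partition_gives_four_bins(self):
        ds = self.make()
        spec = ResponseBinSpec(tc=5.0, bin_size=0.25, min_count=50, vmin=0.0, vmax=1.0)
        bins, report = bin_by_causal_response(ds, spec)
        assert len(bins) == 4

    def test_bin_counts_sum_to_total_retained(self):
        ds = self.make(600, seed=3)
        spec = ResponseBinSpec(tc=5.0, bin_size=0.25, min_count=50, vmin=0.0, vmax=1.0)
        bins, report = bin_by_causal_response(ds, spec)
        assert sum(b.n_cells for b in bins) == report["n_in_bins"]
        assert sum(report["bin_counts"]) + report["n_below_range"] + report["n_above_range"] == 600

    def test_trimmed_tails_reported(self):
        ds = self.make(500, seed=1)
        spec = ResponseBinSpec(tc=5.0, bin_size=0.5, min_count=50, trim_low=10, trim_high=20)
        bins, report = bin_by_causal_response(ds, spec)
        assert report["n_trimmed_low"] == 10
        assert report["n_trimmed_high"] == 20

    def test_min_count_larger_than_n_fails(self):
        ds = self.make(100)
        spec = ResponseBinSpec(tc=5.0, bin_size=0.25, min_count=150, vmin=0.0, vmax=1.0)
        with pytest.raises(ValueError):
            bin_by_causal_response(ds, spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ResponseBinSpec(tc=5.0, bin_size=0.0)
        with pytest.raises(ValueError):
            ResponseBinSpec(tc=5.0, min_count=0)
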