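"""Plan-metric tests: DVH, dose-at-volume, fall-off depths, range shifts,
lateral penumbra."""

import numpy as np
import pytest
from scipy.special import erfc

from protonrbe.grids import ScalarGrid, StructureMask
from protonrbe.metrics import (
    NOT_REACHED, DepthProfile, cumulative_volume_histogram, distal_falloff_depth,
    dose_at_volume, extract_bev_profiles, falloff_gradient, lateral_falloff_8020,
    range_shift, range_shift_analysis, range_shift_summary,
)

EIGHT_VOXELS = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])


def _grid_with_mask(values):
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    g = ScalarGrid(values, (1, 1, 1), (0, 0, 0), "dose_gy")
    m = StructureMask(np.ones_like(values, dtype=bool), "PTV")
    return g, m


def trapezoid(plateau=2.0, flat_to=100.0, zero_at=110.0, z_max=130.0, step=1.0,
              shift=0.0):
    z = np.arange(0.0, z_max + step / 2, step)
    v = np.interp(z, [0.0, flat_to + shift, zero_at + shift],
                  [plateau, plateau, 0.0])
    return DepthProfile(z, v)


class TestVolumeHistogram:
    def test_uniform_grid_is_step_function(self):
        g, m = _grid_with_mask(np.full(10, 1.5))
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        assert h.volume_at(0.0) == 100.0
        assert h.volume_at(1.49) == 100.0
        assert h.volume_at(1.52) == 0.0

    def test_eight_voxel_counts(self):
        g, m = _grid_with_mask(EIGHT_VOXELS)
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        assert h.volume_at(2.5) == pytest.approx(50.0)
        assert h.volume_at(0.0) == 100.0
        # cumulative curve is non-increasing from 100 to 0
        assert h.cumulative_pct[0] == 100.0
        assert h.cumulative_pct[-1] == 0.0
        assert np.all(np.diff(h.cumulative_pct) <= 0)

    def test_empty_mask_rejected(self):
        g, _ = _grid_with_mask(EIGHT_VOXELS)
        m = StructureMask(np.zeros_like(g.values, dtype=bool), "oar")
        with pytest.raises(ValueError, match="empty"):
            cumulative_volume_histogram(g, m)

    def test_nan_voxels_counted_and_dropped(self):
        vals = EIGHT_VOXELS.copy()
        vals[0] = np.nan
        g = ScalarGrid(vals.reshape(-1, 1, 1), (1, 1, 1), (0, 0, 0), "rbe")
        m = StructureMask(np.ones((8, 1, 1), dtype=bool), "PTV")
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        assert h.n_nan == 1
        assert h.volume_at(0.0) == 100.0  # percent of finite volume


class TestDoseAtVolume:
    def test_uniform_grid_any_percentile(self):
        g, m = _grid_with_mask(np.full(10, 2.2))
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        for pct in (5.0, 50.0, 95.0):
            assert dose_at_volume(h, pct) == pytest.approx(2.2, abs=1e-12)

    def test_eight_voxel_median_interpolates(self):
        g, m = _grid_with_mask(EIGHT_VOXELS)
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        assert dose_at_volume(h, 50.0) == pytest.approx(2.5)

    def test_near_minimum_at_95_percent(self):
        g, m = _grid_with_mask(EIGHT_VOXELS)
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        assert 1.0 <= dose_at_volume(h, 95.0) <= 1.5

    def test_out_of_range_percentile_rejected(self):
        g, m = _grid_with_mask(EIGHT_VOXELS)
        h = cumulative_volume_histogram(g, m)
        for bad in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                dose_at_volume(h, bad)

    def test_histogram_only_fallback_close_to_value_based(self):
        rng = np.random.default_rng(7)
        g, m = _grid_with_mask(rng.uniform(0.0, 4.0, size=1000))
        h = cumulative_volume_histogram(g, m, bin_width=0.01)
        h_nov = cumulative_volume_histogram(g, m, bin_width=0.01, keep_values=False)
        for pct in (5.0, 50.0, 95.0):
            assert dose_at_volume(h_nov, pct) == pytest.approx(
                dose_at_volume(h, pct), abs=0.011)


class TestBEVProfiles:
    def test_single_column(self):
        g = ScalarGrid(np.linspace(0, 1, 5).reshape(1, 1, 5) + 1.0,
                       (1, 1, 2.0), (0, 0, 0), "dose_gy")
        profiles = extract_bev_profiles(g, beam_axis=2)
        assert len(profiles) == 1
        np.testing.assert_allclose(profiles[0].depths, [0, 2, 4, 6, 8])

    def test_lateral_count_and_reversal(self):
        g = ScalarGrid(np.ones((3, 3, 6)), (1, 1, 1), (0, 0, 0), "dose_gy")
        g.values[..., -1] = 2.0
        profiles = extract_bev_profiles(g, beam_axis=2)
        assert len(profiles) == 9
        rev = extract_bev_profiles(g, beam_axis=2, direction=-1)
        np.testing.assert_array_equal(rev[0].values[::-1], profiles[0].values)

    def test_invalid_axis_rejected(self):
        g = ScalarGrid(np.ones((2, 2, 2)), (1, 1, 1), (0, 0, 0), "dose_gy")
        with pytest.raises(ValueError, match="axis"):
            extract_bev_profiles(g, beam_axis=3)


class TestDistalFalloff:
    def test_trapezoid_levels(self):
        p = trapezoid()
        assert distal_falloff_depth(p, 0.8, 2.0) == pytest.approx(102.0, abs=1e-9)
        assert distal_falloff_depth(p, 0.5, 2.0) == pytest.approx(105.0, abs=1e-9)

    def test_level_not_reached(self):
        p = trapezoid(plateau=1.0)
        assert distal_falloff_depth(p, 0.9, 2.0) is NOT_REACHED

    def test_distal_most_crossing_wins_over_proximal_dip(self):
        z = np.arange(0.0, 131.0)
        v = np.interp(z, [0, 40, 50, 60, 100, 110], [2.0, 2.0, 1.0, 2.0, 2.0, 0.0])
        p = DepthProfile(z, v)
        # the dip at 50 crosses 80 % too; only the distal fall-off counts
        assert distal_falloff_depth(p, 0.8, 2.0) == pytest.approx(102.0, abs=1e-9)


class TestFalloffGradient:
    def test_trapezoid_gradient(self):
        assert falloff_gradient(trapezoid(), 2.0) == pytest.approx(5.0, abs=1e-9)

    def test_stretched_falloff_is_shallow(self):
        p = trapezoid(flat_to=100.0, zero_at=200.0, z_max=220.0)
        assert falloff_gradient(p, 2.0) == pytest.approx(50.0, abs=1e-9)

    def test_step_function_gradient_near_zero(self):
        # both crossings interpolate inside one sampling interval, so the
        # gradient tends to zero with the step size; always retained
        z = np.arange(0.0, 50.0, 0.01)
        v = np.where(z <= 30, 2.0, 0.0)
        g = falloff_gradient(DepthProfile(z, v), 2.0)
        assert 0.0 <= g < 0.01
        assert g <= 30.0


class TestRangeShift:
    def test_identical_profiles_zero_shift(self):
        p = trapezoid()
        out = range_shift(p, p, d_presc=2.0)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    @pytest.mark.parametrize("delta", [0.6, 1.0, 2.4, 3.0, 5.4])
    def test_translation_recovered_exactly(self, delta):
        ref = trapezoid()
        var = trapezoid(shift=delta)
        out = range_shift(ref, var, d_presc=2.0)
        for lv, v in out.items():
            assert v == pytest.approx(delta, abs=1e-6), lv

    def test_scaled_down_profile_misses_top_level(self):
        ref = trapezoid()
        var = DepthProfile(ref.depths, 0.89 * ref.values)
        out = range_shift(ref, var, levels=(0.9, 0.5), d_presc=2.0)
        assert out[0.9] == "level"
        assert isinstance(out[0.5], float)

    def test_shallow_gradient_excluded(self):
        ref = trapezoid()
        var = trapezoid(flat_to=100.0, zero_at=200.0, z_max=220.0)
        ref2 = trapezoid(z_max=220.0)
        out = range_shift(ref2, var, d_presc=2.0)
        assert all(v == "gradient" for v in out.values())


class TestRangeShiftSummary:
    def test_mean_and_bookkeeping(self):
        per_ray = {
            (0, 0): {0.5: 1.0}, (0, 1): {0.5: 2.0}, (0, 2): {0.5: 3.0},
            (1, 0): {0.5: "gradient"}, (1, 1): {0.5: "level"},
        }
        rs = range_shift_summary(per_ray, map_shape=(2, 3), levels=(0.5,))
        assert rs.mean_shift_mm[0.5] == pytest.approx(2.0)
        assert rs.n_retained[0.5] == 3
        assert rs.n_excluded_gradient[0.5] == 1
        assert rs.n_excluded_level[0.5] == 1
        counts, _ = rs.histograms[0.5]
        assert counts.sum() == rs.n_retained[0.5]
        assert (rs.n_retained[0.5] + rs.n_excluded_gradient[0.5]
                + rs.n_excluded_level[0.5]) == rs.n_rays

    def test_all_rays_equal_shift(self):
        per_ray = {(0, j): {0.8: 2.0} for j in range(4)}
        rs = range_shift_summary(per_ray, (1, 4), levels=(0.8,))
        assert rs.mean_shift_mm[0.8] == pytest.approx(2.0)
        counts, _ = rs.histograms[0.8]
        assert np.count_nonzero(counts) == 1

    def test_zero_retained_is_error(self):
        with pytest.raises(ValueError, match="retained"):
            range_shift_summary({(0, 0): {0.5: "level"}}, (1, 1), levels=(0.5,))


class TestRangeShiftAnalysis:
    def test_uniform_translation_on_grid(self):
        z = np.arange(0.0, 131.0)
        ref_curve = np.interp(z, [0, 100, 110], [2.0, 2.0, 0.0])
        var_curve = np.interp(z, [0, 103, 113], [2.0, 2.0, 0.0])
        ref = ScalarGrid(np.tile(ref_curve, (3, 3, 1)), (1, 1, 1), (0, 0, 0),
                         "drbe_gy_rbe")
        var = ScalarGrid(np.tile(var_curve, (3, 3, 1)), (1, 1, 1), (0, 0, 0),
                         "drbe_gy_rbe")
        rs = range_shift_analysis(ref, var, beam_axis=2, d_presc=2.0)
        for lv in rs.levels:
            assert rs.mean_shift_mm[lv] == pytest.approx(3.0, abs=1e-9)
            assert rs.n_retained[lv] == 9
        assert len(rs.records) == 9 * 3


class TestLateralFalloff:
    @pytest.mark.parametrize("sigma", [5.0, 10.0])
    def test_erfc_edge_width(self, sigma):
        # Gaussian-blurred step: the 80-20 % width is 1.6832 sigma
        x = np.arange(-80.0, 81.0, 1.0)
        v = 0.5 * erfc((x - 30.0) / (np.sqrt(2.0) * sigma))
        lf = lateral_falloff_8020(x, v)
        assert lf.mean_mm == pytest.approx(1.6832 * sigma, rel=0.02)

    def test_ideal_step_edge_width_vanishes_with_sampling(self):
        # both crossings interpolate within the same sample interval
        x = np.arange(-20.0, 21.0, 0.001)
        v = np.where(np.abs(x) <= 10, 1.0, 0.0)
        lf = lateral_falloff_8020(x, v)
        assert lf.mean_mm < 1e-3

    def test_no_crossing_is_error(self):
        x = np.arange(-10.0, 11.0)
        with pytest.raises(ValueError, match="crossing"):
            lateral_falloff_8020(x, np.ones_like(x))
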