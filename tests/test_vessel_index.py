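import numpy as np
import pytest

from conftest import make_geometry
from cvipwi.core import BinaryMask, HemisphereSplit, PerfusionSeries, ScalarMap, split_hemispheres
from cvipwi.errors import DegenerateInputError, UndefinedIndexError
from cvipwi.vessel_index import (
    bolus_peak_index,
    compute_cvi,
    cv_map,
    exclude_ventricles,
    leptomeningeal_mask,
    robust_range,
    strip_low_intensity,
    temporal_stats,
    threshold_highcv,
)
from reference import ref_cv, ref_percentile, ref_temporal_stats


def series_of(data, geometry, tr=1.5):
    return PerfusionSeries(np.asarray(data, float), geometry, tr=tr)


def full_mask(geometry, label="brain"):
    return BinaryMask(np.ones(geometry.shape, bool), geometry, label=label)


class TestTemporalStats:
    def test_constant_series_has_zero_sigma(self, simple_geometry):
        series = series_of(np.full(simple_geometry.shape + (10,), 100.0),
                           simple_geometry)
        sigma, mu = temporal_stats(series, full_mask(simple_geometry))
        assert np.all(sigma.data == 0)
        assert np.all(mu.data == 100.0)

    def test_hand_computed_population_sigma(self, simple_geometry):
        # voxel course (10, 10, 4, 10): mu = 8.5, sigma = sqrt(6.75) with 1/N
        data = np.full(simple_geometry.shape + (4,), 10.0)
        data[0, 0, 0] = [10, 10, 4, 10]
        sigma, mu = temporal_stats(series_of(data, simple_geometry),
                                   full_mask(simple_geometry))
        assert mu.data[0, 0, 0] == pytest.approx(8.5)
        assert sigma.data[0, 0, 0] == pytest.approx(np.sqrt(6.75))
        assert sigma.data[0, 0, 0] == pytest.approx(2.598, abs=1e-3)

    def test_outside_brain_is_zero(self, simple_geometry):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 10, simple_geometry.shape + (6,))
        brain = BinaryMask(np.zeros(simple_geometry.shape, bool), simple_geometry)
        brain.data[0, 0, 0] = True
        sigma, mu = temporal_stats(series_of(data, simple_geometry), brain)
        assert mu.data[1, 1, 1] == 0 and sigma.data[1, 1, 1] == 0
        assert mu.data[0, 0, 0] > 0

    def test_matches_per_voxel_loop_oracle(self):
        g = make_geometry((4, 4, 2))
        rng = np.random.default_rng(42)
        data = rng.uniform(10, 200, g.shape + (10,))
        brain = np.ones(g.shape, bool)
        sigma, mu = temporal_stats(series_of(data, g), BinaryMask(brain, g))
        ref_sigma, ref_mu = ref_temporal_stats(data, brain)
        assert np.max(np.abs(sigma.data - ref_sigma)) < 1e-10
        assert np.max(np.abs(mu.data - ref_mu)) < 1e-10


class TestCvMap:
    def test_hand_computed_ratio(self, simple_geometry):
        sigma = ScalarMap(np.full(simple_geometry.shape, 2.598), simple_geometry)
        mu = ScalarMap(np.full(simple_geometry.shape, 8.5), simple_geometry)
        cv = cv_map(sigma, mu)
        assert cv.data[0, 0, 0] == pytest.approx(0.3056, abs=1e-4)

    def test_zero_mean_guarded(self, simple_geometry):
        sigma = ScalarMap(np.ones(simple_geometry.shape), simple_geometry)
        mu = ScalarMap(np.ones(simple_geometry.shape), simple_geometry)
        mu.data[0, 0, 0] = 0.0
        cv = cv_map(sigma, mu)
        assert cv.data[0, 0, 0] == 0.0
        assert np.all(np.isfinite(cv.data))

    def test_scale_invariance(self, simple_geometry):
        rng = np.random.default_rng(1)
        data = rng.uniform(50, 300, simple_geometry.shape + (12,))
        brain = full_mask(simple_geometry)
        cv1 = cv_map(*temporal_stats(series_of(data, simple_geometry), brain))
        cv7 = cv_map(*temporal_stats(series_of(data * 7, simple_geometry), brain))
        assert np.max(np.abs(cv1.data - cv7.data)) < 1e-12

    def test_matches_loop_oracle(self):
        g = make_geometry((4, 4, 2))
        rng = np.random.default_rng(5)
        data = rng.uniform(10, 200, g.shape + (8,))
        sigma, mu = temporal_stats(series_of(data, g), full_mask(g))
        cv = cv_map(sigma, mu)
        assert np.max(np.abs(cv.data - ref_cv(sigma.data, mu.data))) < 1e-12


class TestRobustRange:
    def geometry_with(self, values):
        n = len(values)
        g = make_geometry((n, 1, 1), voxel_size=(1, 1, 1))
        return ScalarMap(np.asarray(values, float).reshape(n, 1, 1), g), full_mask(g)

    def test_uniform_1_to_100(self):
        m, mask = self.geometry_with(np.arange(1, 101))
        rmin, rmax = robust_range(m, mask)
        assert rmin == pytest.approx(2.98)
        assert rmax == pytest.approx(98.02)
        assert rmin == pytest.approx(ref_percentile(np.arange(1, 101), 2))

    def test_constant_values(self):
        m, mask = self.geometry_with(np.full(150, 3.7))
        assert robust_range(m, mask) == (pytest.approx(3.7), pytest.approx(3.7))

    def test_invariant_to_zero_valued_voxels(self):
        vals = np.arange(1, 151).astype(float)
        m1, mask1 = self.geometry_with(vals)
        m2, mask2 = self.geometry_with(np.concatenate([vals, np.zeros(80)]))
        assert robust_range(m1, mask1) == robust_range(m2, mask2)

    def test_too_few_voxels_degenerate(self):
        m, mask = self.geometry_with(np.arange(1, 50))
        with pytest.raises(DegenerateInputError):
            robust_range(m, mask)


class TestThresholdHighCv:
    def test_threshold_is_midpoint_of_robust_range(self):
        g = make_geometry((100, 1, 1), voxel_size=(1, 1, 1))
        cv = ScalarMap(np.arange(1.0, 101.0).reshape(100, 1, 1), g)
        high, thr = threshold_highcv(cv, full_mask(g))
        assert thr == pytest.approx((2.98 + 98.02) / 2)  # = 50.5
        np.testing.assert_array_equal(high.data.ravel(), np.arange(1, 101) >= thr)

    def test_constant_map_keeps_everything(self):
        g = make_geometry((120, 1, 1), voxel_size=(1, 1, 1))
        cv = ScalarMap(np.full((120, 1, 1), 0.3), g)
        high, thr = threshold_highcv(cv, full_mask(g))
        assert thr == pytest.approx(0.3)
        assert high.count == 120

    def test_recovers_vessel_compartment_on_phantom(self, small_phantom):
        from cvipwi.vessel_index import extract_highcv

        ph = small_phantom
        high, cv, thr, _ = extract_highcv(ph.series, ph.brain, ph.ventricles)
        vessels = ph.vessels.data | ph.sinus.data
        # all true vessel voxels survive and nothing else does
        np.testing.assert_array_equal(high.data, vessels)


class TestBolusPeak:
    def test_gamma_bolus_peak_on_phantom(self, small_phantom):
        ph = small_phantom
        t_star = bolus_peak_index(ph.series, ph.brain)
        expected = (ph.spec.bolus_t0 + ph.spec.bolus_alpha * ph.spec.bolus_beta) / ph.spec.tr
        assert abs(t_star - expected) <= 1

    def test_monotonic_increase_peaks_at_zero(self, simple_geometry):
        t = np.arange(10.0)
        data = np.broadcast_to(100 + t, simple_geometry.shape + (10,)).copy()
        assert bolus_peak_index(series_of(data, simple_geometry),
                                full_mask(simple_geometry)) == 0

    def test_flat_series_tie_breaks_to_zero(self, simple_geometry):
        data = np.full(simple_geometry.shape + (8,), 42.0)
        assert bolus_peak_index(series_of(data, simple_geometry),
                                full_mask(simple_geometry)) == 0


class TestStripLowIntensity:
    def build(self, intensities):
        n = len(intensities)
        g = make_geometry((n, 1, 1), voxel_size=(1, 1, 1))
        data = np.zeros((n, 1, 1, 3))
        data[..., 1] = np.asarray(intensities, float).reshape(n, 1, 1)
        series = series_of(data, g)
        return BinaryMask(np.ones(g.shape, bool), g), series

    def test_removes_exactly_the_lowest_five_percent(self):
        rng = np.random.default_rng(0)
        intensities = rng.permutation(np.arange(100.0) + 1)
        high, series = self.build(intensities)
        out = strip_low_intensity(high, series, t_star=1, fraction=0.05)
        removed = np.flatnonzero(high.data.ravel() & ~out.data.ravel())
        assert sorted(intensities[removed]) == [1, 2, 3, 4, 5]
        assert out.count == 95

    def test_fraction_zero_keeps_mask(self):
        high, series = self.build(np.arange(50.0))
        out = strip_low_intensity(high, series, t_star=1, fraction=0.0)
        np.testing.assert_array_equal(out.data, high.data)

    def test_all_equal_intensities_unchanged(self):
        high, series = self.build(np.full(60, 7.0))
        out = strip_low_intensity(high, series, t_star=1, fraction=0.05)
        np.testing.assert_array_equal(out.data, high.data)

    def test_empty_mask_warns_and_returns_empty(self):
        high, series = self.build(np.arange(20.0))
        empty = BinaryMask(np.zeros(high.geometry.shape, bool), high.geometry)
        with pytest.warns(UserWarning):
            out = strip_low_intensity(empty, series, t_star=1)
        assert out.count == 0

    def test_result_is_subset_of_input(self):
        rng = np.random.default_rng(3)
        high, series = self.build(rng.uniform(0, 50, 80))
        out = strip_low_intensity(high, series, t_star=1, fraction=0.2)
        assert not (out.data & ~high.data).any()


class TestMaskAlgebra:
    def test_exclude_ventricles_count_arithmetic(self, simple_geometry):
        rng = np.random.default_rng(2)
        high = BinaryMask(rng.random(simple_geometry.shape) > 0.3, simple_geometry)
        vent = BinaryMask(rng.random(simple_geometry.shape) > 0.7, simple_geometry)
        overlap = int((high.data & vent.data).sum())
        out = exclude_ventricles(high, vent)
        assert out.count == high.count - overlap

    def test_disjoint_masks_unchanged(self, simple_geometry):
        high = BinaryMask(np.zeros(simple_geometry.shape, bool), simple_geometry)
        high.data[0] = True
        vent = BinaryMask(np.zeros(simple_geometry.shape, bool), simple_geometry)
        vent.data[-1] = True
        np.testing.assert_array_equal(exclude_ventricles(high, vent).data, high.data)

    def test_superset_ventricles_empty_result(self, simple_geometry):
        high = BinaryMask(np.ones(simple_geometry.shape, bool), simple_geometry)
        assert exclude_ventricles(high, high).count == 0

    def test_leptomeningeal_mask_from_atlas(self, simple_geometry):
        density = ScalarMap(np.zeros(simple_geometry.shape), simple_geometry)
        density.data[2:5] = 1.5
        sinus = BinaryMask(np.zeros(simple_geometry.shape, bool), simple_geometry)
        sinus.data[3] = True
        lepto = leptomeningeal_mask(density, sinus)
        assert lepto.count == int((density.data > 0).sum() - sinus.count)
        # zero-density atlas -> empty; empty sinus -> full support
        empty = leptomeningeal_mask(
            ScalarMap(np.zeros(simple_geometry.shape), simple_geometry), sinus)
        assert empty.count == 0
        full = leptomeningeal_mask(density, BinaryMask(
            np.zeros(simple_geometry.shape, bool), simple_geometry))
        assert full.count == int((density.data > 0).sum())


class TestComputeCvi:
    def split_of(self, geometry):
        return split_hemispheres(
            BinaryMask(np.ones(geometry.shape, bool), geometry), "left")

    def test_known_volume_ratio(self):
        g = make_geometry((8, 4, 2))
        high = np.zeros(g.shape, bool)
        high[0:2] = True   # 16 voxels left (affected)
        high[6:8] = True
        high[7, :, 1] = False  # 12 voxels right
        result = compute_cvi(BinaryMask(high, g), self.split_of(g), g)
        assert result.highcv_affected_mm3 == pytest.approx(16 * g.voxel_volume)
        assert result.highcv_unaffected_mm3 == pytest.approx(12 * g.voxel_volume)
        assert result.cvi == pytest.approx(16 / 12)

    def test_zero_unaffected_volume_is_an_error(self):
        g = make_geometry((8, 4, 2))
        high = np.zeros(g.shape, bool)
        high[0] = True
        with pytest.raises(UndefinedIndexError):
            compute_cvi(BinaryMask(high, g), self.split_of(g), g)

    @pytest.mark.parametrize(
        "cvi,expected",
        [(0.963, "good_moderate"), (1.2, "good_moderate"), (0.962, "poor"), (0.3, "poor")],
    )
    def test_dichotomization_cutoff(self, cvi, expected):
        g = make_geometry((4, 2, 2))
        high = np.zeros(g.shape, bool)
        high[0], high[3] = True, True
        result = compute_cvi(BinaryMask(high, g), self.split_of(g), g)
        result.cvi = cvi
        assert result.dichotomize(0.963) == expected
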