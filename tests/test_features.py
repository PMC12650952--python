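"""Radius of gyration, ROI intensity, threshold fitting and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import digichamber as dc
from digichamber.features import NEGATIVE, POSITIVE

from conftest import rog_brute_force

UNIFORM_16 = math.sqrt(42.5)  # ROG of a uniform 16x16 crop


class TestRadiusOfGyration:
    def test_uniform_crop_hits_closed_form(self):
        assert dc.radius_of_gyration(np.full((16, 16), 7.3)) == pytest.approx(UNIFORM_16)
        assert dc.uniform_rog(16) == pytest.approx(UNIFORM_16)

    def test_single_pixel_is_distance_to_center(self):
        crop = np.zeros((16, 16))
        crop[8, 8] = 5.0
        # pixel (8, 8) sits sqrt(0.5) px from the geometric center (7.5, 7.5)
        assert dc.radius_of_gyration(crop) == pytest.approx(math.sqrt(0.5))

    def test_centered_disk_lands_in_derived_band(self):
        yy, xx = np.mgrid[0:16, 0:16]
        disk = (((xx - 7.5) ** 2 + (yy - 7.5) ** 2) <= 25.0).astype(float)
        value = dc.radius_of_gyration(disk)
        assert value == pytest.approx(rog_brute_force(disk))
        assert 3.0 <= value <= 4.2 < UNIFORM_16

    def test_matches_brute_force_on_random_crops(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m, n = rng.integers(2, 24, size=2)
            crop = rng.random((m, n)) * rng.uniform(0.1, 1000)
            assert dc.radius_of_gyration(crop) == pytest.approx(
                rog_brute_force(crop), rel=1e-12)

    def test_all_zero_crop_is_undefined(self):
        with pytest.raises(dc.UndefinedROGError):
            dc.radius_of_gyration(np.zeros((16, 16)))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            dc.radius_of_gyration(np.full((4, 4), -1.0))

    def test_optional_min_subtraction_sharpens_a_spot_on_background(self):
        yy, xx = np.mgrid[0:16, 0:16]
        r2 = (xx - 7.5) ** 2 + (yy - 7.5) ** 2
        crop = 100.0 + 500.0 * np.exp(-r2 / 8.0)
        raw = dc.radius_of_gyration(crop)
        cleaned = dc.radius_of_gyration(crop, subtract_min=True)
        assert cleaned < raw  # removing the pedestal concentrates the mass
        assert cleaned == pytest.approx(
            dc.radius_of_gyration(crop - crop.min()))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariant_offset_sensitive_and_bounded(self, seed):
        """On background-plus-centered-spot crops (the assay's geometry), ROG
        ignores multiplicative rescaling, stays below the uniform-crop value,
        and an additive offset pushes it toward (not past) that value."""
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[0:16, 0:16]
        r2 = (xx - 7.5) ** 2 + (yy - 7.5) ** 2
        spot = rng.uniform(10, 500) * np.exp(-r2 / (2 * rng.uniform(1.0, 3.0) ** 2))
        crop = rng.uniform(0, 20) + spot
        value = dc.radius_of_gyration(crop)
        assert dc.radius_of_gyration(3.7 * crop) == pytest.approx(value, rel=1e-12)
        assert value < UNIFORM_16
        shifted = dc.radius_of_gyration(crop + 500.0)
        assert value < shifted < UNIFORM_16

    def test_corner_concentration_exceeds_uniform_value(self):
        """ROG is a weighted mean of pixel radius, so the uniform crop is not
        an upper bound: corner-concentrated intensity exceeds it (this is why
        the classifier thresholds at 5.5 rather than 'anything below 6.52')."""
        crop = np.zeros((16, 16))
        crop[0, 0] = 1.0
        assert dc.radius_of_gyration(crop) == pytest.approx(7.5 * math.sqrt(2))
        assert dc.radius_of_gyration(crop) > UNIFORM_16


class TestMeanRoiIntensity:
    def test_constant_image(self):
        roi = dc.ChamberROI(0, 20.0, 20.0)
        image = np.full((40, 40), 3.25)
        assert dc.mean_roi_intensity(image, roi) == pytest.approx(3.25)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        image = rng.random((40, 40))
        roi = dc.ChamberROI(0, 17.3, 21.8)
        assert dc.mean_roi_intensity(2 * image, roi) == pytest.approx(
            2 * dc.mean_roi_intensity(image, roi))

    def test_concentric_disk_mean_nearly_full(self):
        """10-px disk of value 100: the ROI may clip boundary pixels, but the
        exact pixel-in-circle oracle says the mean stays >= 95."""
        yy, xx = np.mgrid[0:40, 0:40]
        inside = ((xx - 20.0) ** 2 + (yy - 20.0) ** 2) <= 25.0
        image = np.where(inside, 100.0, 0.0)
        roi = dc.ChamberROI(0, 20.0, 20.0, roi_diameter_px=10.0)
        oracle = image[inside].sum() / inside.sum()  # ROI mask == disk mask here
        value = dc.mean_roi_intensity(image, roi)
        assert value == pytest.approx(oracle)
        assert value >= 95.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            dc.mean_roi_intensity(np.ones((20, 20)), dc.ChamberROI(0, 2.0, 2.0))


class TestFitIntensityThreshold:
    def test_gaussian_sample_recovers_mu_plus_15_sigma(self):
        rng = np.random.default_rng(123)
        values = rng.normal(100.0, 5.0, size=10_000)
        thr = dc.fit_intensity_threshold(values, k_sd=15.0)
        assert thr.fit_method == "gaussian_fit"
        assert thr.intensity_threshold == pytest.approx(175.0, abs=3.0)

    def test_contaminated_sample_locks_onto_dominant_mode(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.normal(100.0, 5.0, size=9_500),
                                 rng.normal(400.0, 10.0, size=500)])
        thr = dc.fit_intensity_threshold(values)
        assert 98.0 <= thr.intensity_mu <= 102.0
        assert values.mean() > 110.0  # the plain mean is dragged by the contaminant

    def test_identical_values_raise(self):
        with pytest.raises(ValueError):
            dc.fit_intensity_threshold(np.full(500, 42.0))

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            dc.fit_intensity_threshold(np.random.default_rng(0).normal(size=50))

    def test_data_driven_rog_threshold_is_a_low_percentile(self):
        rng = np.random.default_rng(5)
        rogs = rng.normal(6.5, 0.05, size=5000)  # negatives hover near uniform
        thr = dc.rog_threshold_from_negatives(rogs, percentile=0.5)
        assert thr == pytest.approx(np.percentile(rogs, 0.5))
        assert (rogs < thr).mean() <= 0.006


class TestClassify:
    THR = dc.ThresholdSet(intensity_mu=100.0, intensity_sigma=2.0, k_sd=15.0,
                          rog_threshold=5.5)  # intensity threshold 130

    def _m(self, rog, intensity, excluded=False):
        return dc.ChamberMeasurement(0, mean_intensity=intensity, rog=rog,
                                     excluded=excluded)

    @pytest.mark.parametrize("rog,intensity,label", [
        (6.4, 1300.0, NEGATIVE),      # ROG gate fires first, however bright
        (3.5, 130.0, NEGATIVE),       # tie on intensity -> negative
        (3.5, 130.0 + 1e-9, POSITIVE),
        (5.5, 131.0, POSITIVE),       # tie on ROG passes the gate (strict >)
        (float("nan"), 500.0, NEGATIVE),
        (2.0, 50.0, NEGATIVE),
    ])
    def test_logic_tree(self, rog, intensity, label):
        assert dc.classify(self._m(rog, intensity), self.THR) == label

    def test_excluded_always_negative(self):
        assert dc.classify(self._m(3.0, 1e6, excluded=True), self.THR) == NEGATIVE

    def test_pure_function(self):
        m = self._m(3.0, 200.0)
        assert dc.classify(m, self.THR) == dc.classify(m, self.THR) == POSITIVE


class TestApplyExclusions:
    def _measurements(self):
        return [dc.ChamberMeasurement(i, 200.0, 3.0, label=POSITIVE) for i in range(5)]

    def test_empty_list_is_identity(self):
        ms = self._measurements()
        assert dc.apply_exclusions(ms, []) == ms

    def test_exclusion_flags_and_denominator(self):
        ms = dc.apply_exclusions(self._measurements(), [1, 3])
        assert sum(m.excluded for m in ms) == 2
        assert len(ms) == 5  # raw total unchanged
        q = dc.summarize_counts(5, sum(m.label == POSITIVE for m in ms), 2,
                                chamber_volume_L=4.364e-14)
        assert q.positive_fraction == pytest.approx(3 / 3)

    def test_excluding_all_positives_zeroes_the_count(self):
        ms = dc.apply_exclusions(self._measurements(), list(range(5)))
        assert sum(m.label == POSITIVE for m in ms) == 0
        assert len(ms) == 5

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            dc.apply_exclusions(self._measurements(), [99])
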