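"""Profile extraction, Gaussian peak refinement and half-maximum boundaries."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from aslheight import (
    ZProfile,
    classify_interfaces,
    detect_reflection_peaks,
    extract_profile,
    fit_gaussian_peak,
    half_max_bounds,
)
from aslheight.errors import BoundaryFailureError, InsufficientPeaksError
from aslheight.profiles import PeakFit


def make_profile(y, z_spacing=0.1, channel="reflection"):
    return ZProfile(np.asarray(y, dtype=float), z_spacing=z_spacing, channel=channel)


def gaussian_trace(z, center, sigma, amp=1.0, base=0.0):
    return amp * np.exp(-((z - center) ** 2) / (2 * sigma**2)) + base


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        image = np.full((9, 20), 7.0)
        prof = extract_profile(image, 4, width=5, z_spacing=0.2)
        assert np.all(prof.intensities == 7.0)
        assert prof.intensities.size == 20

    def test_width_one_copies_the_column(self):
        image = np.arange(60.0).reshape(3, 20)
        prof = extract_profile(image, 2, width=1, z_spacing=0.2)
        assert np.array_equal(prof.intensities, image[2])

    def test_width_three_averages_columns(self):
        image = np.stack([np.full(12, v) for v in (1.0, 2.0, 3.0)])
        prof = extract_profile(image, 1, width=3, z_spacing=0.2)
        assert np.all(prof.intensities == 2.0)

    def test_window_outside_image_raises(self):
        with pytest.raises(IndexError):
            extract_profile(np.ones((4, 20)), 0, width=5, z_spacing=0.2)


class TestGaussianFit:
    def test_recovers_subpixel_center_of_clean_gaussian(self):
        z = np.arange(0, 20, 0.2)
        prof = make_profile(gaussian_trace(z, 10.30, 0.8), z_spacing=0.2)
        fit = fit_gaussian_peak(prof, window_center=10.2, window_halfwidth=2.0)
        assert fit.center == pytest.approx(10.30, abs=1e-3)
        assert fit.sigma == pytest.approx(0.8, abs=1e-2)
        assert fit.r_squared > 0.999

    def test_constant_baseline_does_not_move_the_center(self):
        z = np.arange(0, 20, 0.2)
        clean = make_profile(gaussian_trace(z, 10.30, 0.8), z_spacing=0.2)
        raised = make_profile(gaussian_trace(z, 10.30, 0.8, base=5.0), z_spacing=0.2)
        f0 = fit_gaussian_peak(clean, 10.2)
        f5 = fit_gaussian_peak(raised, 10.2)
        assert f5.center == pytest.approx(f0.center, abs=1e-6)
        assert f5.baseline == pytest.approx(5.0, abs=1e-3)

    def test_center_error_under_noise_is_small(self):
        # Monte-Carlo: 5 % amplitude noise, 200 seeded replicates
        z = np.arange(0, 20, 0.2)
        clean = gaussian_trace(z, 10.30, 0.8)
        rng = np.random.default_rng(1234)
        errors = []
        for _ in range(200):
            noisy = clean + rng.normal(0, 0.05, z.size)
            fit = fit_gaussian_peak(make_profile(noisy, 0.2), 10.2)
            errors.append(abs(fit.center - 10.30))
        assert np.mean(errors) < 0.05


class TestPeakDetection:
    def _triple(self, bump=None):
        z = np.arange(0, 30, 0.2)
        y = (gaussian_trace(z, 2.0, 0.6, 0.6) + gaussian_trace(z, 8.0, 0.6, 0.4)
             + gaussian_trace(z, 20.0, 0.6, 1.0))
        if bump is not None:
            y = y + gaussian_trace(z, 14.0, 0.6, bump)
        return make_profile(y, 0.2)

    def test_finds_three_gaussians_at_their_centers(self):
        fits = detect_reflection_peaks(self._triple())
        assert len(fits) == 3
        for fit, c in zip(fits, (2.0, 8.0, 20.0)):
            assert fit.center == pytest.approx(c, abs=0.2)

    def test_subthreshold_bump_is_ignored(self):
        fits = detect_reflection_peaks(self._triple(bump=0.05), min_prominence=0.1)
        assert len(fits) == 3

    def test_two_peaks_is_insufficient(self):
        z = np.arange(0, 30, 0.2)
        y = gaussian_trace(z, 5.0, 0.6) + gaussian_trace(z, 15.0, 0.6)
        with pytest.raises(InsufficientPeaksError):
            detect_reflection_peaks(make_profile(y, 0.2))


class TestClassifyInterfaces:
    @staticmethod
    def peak(center, prominence=1.0):
        return PeakFit(center=center, sigma=0.7, amplitude=1.0, baseline=0.0,
                       r_squared=1.0, prominence=prominence)

    def test_assigns_by_ascending_depth(self):
        ifc = classify_interfaces([self.peak(11.0), self.peak(3.0), self.peak(26.0)])
        assert (ifc.z1_medium_transwell, ifc.z2_transwell_cell, ifc.z3_asl_air) == (3.0, 11.0, 26.0)

    def test_weakest_of_four_peaks_is_dropped(self):
        peaks = [self.peak(3.0), self.peak(11.0), self.peak(14.0, prominence=0.1),
                 self.peak(26.0)]
        ifc = classify_interfaces(peaks)
        assert ifc.z2_transwell_cell == 11.0
        assert ifc.z3_asl_air == 26.0

    def test_prominence_tie_broken_toward_shallower_depth(self):
        peaks = [self.peak(3.0), self.peak(11.0), self.peak(14.0, prominence=1.0),
                 self.peak(26.0, prominence=2.0)]
        ifc = classify_interfaces(peaks)
        # 3.0 and 11.0 tie with 14.0 at prominence 1.0; shallower ones win
        assert (ifc.z1_medium_transwell, ifc.z2_transwell_cell, ifc.z3_asl_air) == (3.0, 11.0, 26.0)

    def test_fewer_than_three_raises(self):
        with pytest.raises(InsufficientPeaksError):
            classify_interfaces([self.peak(3.0), self.peak(11.0)])

    def test_phantom_interfaces_match_truth(self, noiseless_scan):
        prof = extract_profile(noiseless_scan.reflection_image, 32, 5,
                               z_spacing=noiseless_scan.z_spacing)
        ifc = classify_interfaces(detect_reflection_peaks(prof))
        t = noiseless_scan.truth
        dz = noiseless_scan.z_spacing
        assert ifc.z1_medium_transwell == pytest.approx(t.z1, abs=dz)
        assert ifc.z2_transwell_cell == pytest.approx(t.z2, abs=dz)
        assert ifc.z3_asl_air == pytest.approx(t.z3, abs=dz)


class TestHalfMaxBounds:
    def test_triangle_bounds_near_half_of_apex(self):
        # apex 100 at z=10, zeros at 6 and 14: exact half-max edges are (8, 12);
        # the plateau-core reference reads slightly below a pointed apex, so a
        # few tenths of slack are allowed (plateaus, the real use, are exact)
        z = np.arange(0, 20, 0.1)
        y = np.clip(100 * (1 - np.abs(z - 10.0) / 4.0), 0, None)
        b = half_max_bounds(make_profile(y, 0.1, "calcein"))
        assert b.z_lower == pytest.approx(8.0, abs=0.3)
        assert b.z_upper == pytest.approx(12.0, abs=0.3)

    def test_rectangular_band_edges(self):
        z = np.arange(0, 20, 0.1)
        y = ((z >= 5.0) & (z < 12.0)).astype(float)
        b = half_max_bounds(make_profile(y, 0.1, "calcein"))
        assert b.z_lower == pytest.approx(5.0, abs=0.1)
        assert b.z_upper == pytest.approx(12.0, abs=0.1)

    def test_blurred_step_recovers_true_edges(self):
        # numeric convolution oracle: a step blurred by a Gaussian crosses
        # half of the plateau exactly at the original edge
        dz = 0.05
        z = np.arange(0, 20, dz)
        y = gaussian_filter1d(((z >= 5.0) & (z < 12.0)).astype(float), 0.7 / dz)
        b = half_max_bounds(make_profile(y, dz, "rhodamine"))
        assert b.z_lower == pytest.approx(5.0, abs=0.05)
        assert b.z_upper == pytest.approx(12.0, abs=0.05)

    def test_flat_profile_has_no_band(self):
        with pytest.raises(BoundaryFailureError):
            half_max_bounds(make_profile(np.zeros(50), 0.2, "rhodamine"))

    def test_band_running_off_the_stack_fails(self):
        z = np.arange(0, 20, 0.1)
        y = (z >= 15.0).astype(float)  # upper edge never comes back down
        with pytest.raises(BoundaryFailureError):
            half_max_bounds(make_profile(y, 0.1, "rhodamine"))
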