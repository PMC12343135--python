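"""Multi-Gaussian peak fitting and the PSF-convolved disc model."""

import numpy as np
import pytest

from myomorph import (
    GaussianPeakSet,
    IntensityProfile,
    detect_peaks,
    disc_model,
    fit_disc,
    fit_gaussian_peaks,
    measure_diameter,
    naive_fwhm,
    sarcomere_lengths,
)
from myomorph.errors import (
    DegenerateProfile,
    NoPeaks,
    TooFewPeaks,
)
from tests.conftest import PIXEL


def gaussian_profile(centers, sigma=0.2, amp=100.0, base=0.0, step=0.05,
                     lo=0.0, hi=None, noise_rng=None):
    if hi is None:
        hi = max(centers) + 2.0
    x = np.arange(lo, hi, step)
    y = np.full_like(x, base)
    for c in centers:
        y = y + amp * np.exp(-((x - c) ** 2) / (2 * sigma ** 2))
    if noise_rng is not None:
        y = noise_rng.poisson(np.clip(y, 0, None)).astype(float)
    return IntensityProfile(x, y, "longitudinal")


class TestDetectPeaks:
    def test_constant_profile_raises(self):
        prof = IntensityProfile(np.arange(20) * 0.1, np.full(20, 3.0),
                                "longitudinal")
        with pytest.raises(NoPeaks):
            detect_peaks(prof)

    def test_two_clean_gaussians(self):
        prof = gaussian_profile([2.0, 5.0])
        pos = detect_peaks(prof)
        assert len(pos) == 2
        assert np.allclose(pos, [2.0, 5.0], atol=0.05)

    def test_simulated_zdisc_profile_has_seven_peaks(self, noisy_image,
                                                     straight_spec):
        from tests.test_profile import straight_centerline
        from myomorph import longitudinal_profile

        # extend 1 um past each end so the terminal Z-discs are interior
        # maxima of the sampled profile
        cl = straight_centerline(
            straight_spec.origin[0] - 1.0,
            straight_spec.origin[0] + straight_spec.length + 1.0,
            straight_spec.origin[1],
        )
        prof = longitudinal_profile(noisy_image.zdisc_channel, PIXEL, cl)
        assert len(detect_peaks(prof)) == 7


class TestFitGaussianPeaks:
    def test_noiseless_single_peak_recovery(self):
        prof = gaussian_profile([5.0], sigma=0.2, amp=100.0, base=0.0,
                                step=0.05, hi=10.0)
        fit = fit_gaussian_peaks(prof)
        assert fit.n_peaks == 1
        assert fit.centers[0] == pytest.approx(5.0, abs=0.005)
        assert fit.sigmas[0] == pytest.approx(0.2, rel=0.05)

    def test_six_peaks_uniform_spacing_recovered(self):
        centers = 1.0 + 3.2 * np.arange(6)
        prof = gaussian_profile(centers, sigma=0.15, hi=18.5)
        fit = fit_gaussian_peaks(prof)
        diffs = np.diff(fit.centers)
        assert np.allclose(diffs, 3.2, atol=0.01)

    def test_poisson_noise_center_scatter_small(self):
        # 100-count peaks: the fitted centre scatters by far less than a
        # pixel across noise realisations
        centers = [2.0, 5.2, 8.4]
        est = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            prof = gaussian_profile(centers, sigma=0.15, amp=100.0,
                                    base=5.0, hi=10.5, noise_rng=rng)
            fit = fit_gaussian_peaks(prof)
            if fit.n_peaks == 3:
                est.append(fit.centers[1])
        assert len(est) > 90
        assert np.std(est) < 0.02

    def test_scale_equivariance(self):
        prof = gaussian_profile([2.0, 5.0], base=10.0, hi=7.5)
        scaled = IntensityProfile(prof.positions, prof.values * 3.0,
                                  "longitudinal")
        a, b = fit_gaussian_peaks(prof), fit_gaussian_peaks(scaled)
        assert np.allclose(a.centers, b.centers, atol=1e-6)
        assert np.allclose(a.sigmas, b.sigmas, rtol=1e-4)
        assert np.allclose(b.amplitudes, 3 * a.amplitudes, rtol=1e-3)

    def test_translation_equivariance(self):
        prof = gaussian_profile([2.0, 5.0], hi=7.5)
        shifted = IntensityProfile(prof.positions + 1.25, prof.values,
                                   "longitudinal")
        a, b = fit_gaussian_peaks(prof), fit_gaussian_peaks(shifted)
        assert np.allclose(b.centers - a.centers, 1.25, atol=1e-6)


class TestSarcomereLengths:
    def _peakset(self, centers):
        n = len(centers)
        return GaussianPeakSet(np.asarray(centers, float), np.full(n, 0.1),
                               np.full(n, 100.0), 0.0, 0.0, True)

    def test_successive_differences(self):
        sl = sarcomere_lengths(self._peakset([0.0, 3.2, 6.4]),
                               exclude_terminal=False)
        assert np.allclose(sl.distances, [3.2, 3.2])

    def test_exclude_terminal_drops_first_and_last(self):
        sl = sarcomere_lengths(self._peakset([0, 3.2, 6.4, 9.6, 12.8]),
                               exclude_terminal=True)
        assert np.allclose(sl.distances, [3.2, 3.2])

    def test_mean_and_sd_match_distances(self):
        sl = sarcomere_lengths(self._peakset([0, 3.0, 6.4, 9.5]),
                               exclude_terminal=False)
        assert sl.mean == pytest.approx(np.mean(sl.distances))
        assert sl.sd == pytest.approx(np.std(sl.distances, ddof=1))

    def test_too_few_peaks_raises(self):
        with pytest.raises(TooFewPeaks):
            sarcomere_lengths(self._peakset([0.0, 3.2]),
                              exclude_terminal=True)


class TestDiscModel:
    def test_sharp_disc_endpoints(self):
        x = np.array([-0.75, 0.0, 0.75])
        y = disc_model(x, 0.0, 0.75, 0.0, 100.0, 10.0)
        assert y[1] == pytest.approx(110.0)
        assert y[0] == pytest.approx(10.0)
        assert y[2] == pytest.approx(10.0)

    def test_even_symmetry(self):
        x = np.linspace(-2, 2, 401)
        y = disc_model(x, 0.0, 0.75, 0.12, 50.0, 5.0)
        assert np.allclose(y, y[::-1], rtol=1e-6, atol=1e-6)

    def test_sharp_disc_fwhm_is_sqrt3_R(self):
        R = 0.75
        x = np.arange(-2.0, 2.0, 0.001)
        prof = IntensityProfile(x, disc_model(x, 0.0, R, 0.0, 100.0, 0.0),
                                "transverse")
        assert naive_fwhm(prof) == pytest.approx(np.sqrt(3) * R, rel=1e-3)


class TestFitDisc:
    def test_self_model_recovery(self):
        x = np.arange(-2.5, 2.5001, 0.025)
        y = disc_model(x, 0.0, 0.75, 0.10, 100.0, 10.0)
        fit = fit_disc(IntensityProfile(x, y, "transverse"))
        assert fit.diameter == pytest.approx(1.50, rel=0.01)
        assert fit.converged

    def test_airy_blurred_fibril_within_3_percent(self, noiseless_image,
                                                  straight_spec):
        from myomorph import transverse_profile
        from tests.test_profile import straight_centerline

        cl = straight_centerline(
            straight_spec.origin[0] + 2.0,
            straight_spec.origin[0] + straight_spec.length - 2.0,
            straight_spec.origin[1],
        )
        prof = transverse_profile(noiseless_image.phalloidin_channel, PIXEL,
                                  cl, at_arclength=cl.length / 2)
        fit = fit_disc(prof)
        assert fit.diameter == pytest.approx(1.5, rel=0.03)

    def test_fwhm_underestimates_where_disc_fit_does_not(self):
        # the manual-measurement bias: FWHM of the bare projected cylinder
        # is sqrt(3)/2 ~ 0.87 of the true diameter
        R = 0.75
        x = np.arange(-2.5, 2.5001, 0.005)
        y = disc_model(x, 0.0, R, 0.0, 100.0, 10.0)
        prof = IntensityProfile(x, y, "transverse")
        assert naive_fwhm(prof) / (2 * R) == pytest.approx(0.866, abs=0.01)
        fit = fit_disc(prof)
        assert fit.diameter == pytest.approx(2 * R, rel=0.01)

    def test_flat_profile_rejected(self):
        prof = IntensityProfile(np.arange(20) * 0.1, np.full(20, 5.0),
                                "transverse")
        with pytest.raises(DegenerateProfile):
            fit_disc(prof)

    def test_scale_and_translation_equivariance(self):
        x = np.arange(-2.5, 2.5001, 0.025)
        y = disc_model(x, 0.2, 0.6, 0.08, 80.0, 10.0)
        a = fit_disc(IntensityProfile(x, y, "transverse"))
        b = fit_disc(IntensityProfile(x, 2.5 * y, "transverse"))
        c = fit_disc(IntensityProfile(x + 1.0, y, "transverse"))
        assert b.radius == pytest.approx(a.radius, rel=1e-3)
        assert b.amplitude == pytest.approx(2.5 * a.amplitude, rel=1e-2)
        assert c.center - a.center == pytest.approx(1.0, abs=1e-3)


class TestMeasureDiameter:
    def test_constant_diameter_median_matches_positions(self, noiseless_image,
                                                        straight_spec):
        from tests.test_profile import straight_centerline

        cl = straight_centerline(
            straight_spec.origin[0] + 1.5,
            straight_spec.origin[0] + straight_spec.length - 1.5,
            straight_spec.origin[1],
        )
        dm = measure_diameter(noiseless_image.phalloidin_channel, PIXEL, cl,
                              n_positions=6)
        diams = [f.diameter for f in dm.fits if f is not None and f.converged]
        assert np.allclose(diams, dm.diameter, rtol=0.02)

    def test_single_position_returns_that_fit(self, noiseless_image,
                                              straight_spec):
        from tests.test_profile import straight_centerline

        cl = straight_centerline(
            straight_spec.origin[0] + 1.5,
            straight_spec.origin[0] + straight_spec.length - 1.5,
            straight_spec.origin[1],
        )
        dm = measure_diameter(noiseless_image.phalloidin_channel, PIXEL, cl,
                              n_positions=1)
        assert len(dm.fits) == 1
        assert dm.diameter == pytest.approx(dm.fits[0].diameter)

    def test_noisy_fixture_within_5_percent(self, noisy_image, straight_spec):
        from tests.test_profile import straight_centerline

        cl = straight_centerline(
            straight_spec.origin[0] + 1.5,
            straight_spec.origin[0] + straight_spec.length - 1.5,
            straight_spec.origin[1],
        )
        dm = measure_diameter(noisy_image.phalloidin_channel, PIXEL, cl)
        assert dm.diameter == pytest.approx(1.5, rel=0.05)
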