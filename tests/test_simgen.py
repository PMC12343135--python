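"""Ground-truth rendering, Airy PSF and the noise pipeline."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label
from scipy.optimize import brentq
from scipy.special import j1

from myomorph import (
    ImagingSpec,
    MyofibrilSpec,
    airy_psf,
    render_ground_truth,
    simulate_image,
)
from myomorph.errors import InvalidSpec, SpecOutOfCanvas
from myomorph.simgen import _convolve_reflect


class TestRenderGroundTruth:
    def test_empty_scene_is_all_zero(self, imaging):
        img = render_ground_truth([], imaging, (50, 60))
        assert img.phalloidin_channel.shape == (50, 60)
        assert not img.phalloidin_channel.any()
        assert not img.zdisc_channel.any()

    def test_zdisc_channel_has_n_plus_one_bands(self, ground_truth):
        _, n = cc_label(ground_truth.zdisc_channel > 0)
        assert n == 7  # 6 sarcomeres -> 7 Z-discs

    def test_transverse_extent_matches_diameter(self, imaging):
        # axis midway between two pixel-row centres: a 1.5 um cylinder at
        # 50 nm pixels covers exactly 30 rows
        spec = MyofibrilSpec(6, 3.2, 1.5, origin=(1.0, 3.525))
        img = render_ground_truth([spec], imaging, (150, 450))
        interior_cols = range(100, 300)
        runs = {np.count_nonzero(img.phalloidin_channel[:, c])
                for c in interior_cols}
        # H-zone columns are empty; every labelled column spans 30 px
        assert runs - {0} == {30}

    def test_axial_structure_overlap_gap_and_bulk(self, ground_truth, straight_spec):
        ph = ground_truth.phalloidin_channel
        row = int(round(straight_spec.origin[1] / ground_truth.pixel_size))
        col_of = lambda s: int(round((straight_spec.origin[0] + s) / ground_truth.pixel_size))
        z = ph[row, col_of(3.2)]           # on a Z-line: doubled overlap
        bulk = ph[row, col_of(3.2 / 4)]    # thin-filament region
        h = ph[row, col_of(3.2 / 2)]       # H-zone gap
        assert z == pytest.approx(100.0)
        assert bulk == pytest.approx(50.0, rel=0.02)
        assert h == 0.0

    def test_zdisc_total_intensity_linear_in_band_count(self, imaging):
        totals = []
        for n in (2, 3, 4, 5):
            spec = MyofibrilSpec(n, 3.2, 1.5, origin=(2.0, 3.5))
            img = render_ground_truth([spec], imaging, (140, 470))
            totals.append(img.zdisc_channel.sum() / (n + 1))
        assert np.ptp(totals) / np.mean(totals) < 0.01

    def test_rotating_spec_matches_rotating_canvas(self, imaging):
        n = 241  # odd square so pixel centres map onto pixel centres
        c = (n - 1) / 2 * imaging.pixel_size
        horiz = MyofibrilSpec(2, 3.2, 1.0, orientation=0.0,
                              origin=(c - 3.2, c))
        vert = MyofibrilSpec(2, 3.2, 1.0, orientation=90.0,
                             origin=(c, c - 3.2))
        a = render_ground_truth([horiz], imaging, (n, n)).phalloidin_channel
        b = render_ground_truth([vert], imaging, (n, n)).phalloidin_channel
        # rot90 maps the horizontal fibril onto the vertical one
        assert np.max(np.abs(np.rot90(a, k=-1) - b)) < 0.01 * a.max()

    def test_out_of_canvas_raises(self, imaging):
        spec = MyofibrilSpec(6, 3.2, 1.5, origin=(2.0, 3.5))
        with pytest.raises(SpecOutOfCanvas):
            render_ground_truth([spec], imaging, (140, 100))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_sarcomeres=-1, sarcomere_length=3.2, diameter=1.5),
            dict(n_sarcomeres=3, sarcomere_length=3.2, diameter=0.0),
            dict(n_sarcomeres=3, sarcomere_length=3.2, diameter=1.5,
                 zdisc_width=3.3),
            dict(n_sarcomeres=3, sarcomere_length=3.2, diameter=1.5,
                 zdisc_width=1.7, hzone_width=1.7),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpec):
            MyofibrilSpec(**kwargs)


class TestAiryPsf:
    def test_kernel_normalised_and_symmetric(self, imaging):
        k = airy_psf(imaging, kernel_radius=15)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(k, k[::-1, ::-1])
        assert np.allclose(k, k.T)

    def test_first_dark_ring_position(self, imaging):
        # independent oracle: first root of J1 -> r0 = 3.8317 lam / (2 pi NA)
        root = brentq(j1, 2.0, 5.0)
        r0_nm = root * imaging.emission_wavelength / (
            2 * np.pi * imaging.numerical_aperture
        )
        assert r0_nm == pytest.approx(228.7, abs=0.1)
        k = airy_psf(imaging, kernel_radius=15)
        centre = k.shape[0] // 2
        radial = k[centre, centre:]
        first_min_px = np.argmin(np.diff(radial) < 0)  # first non-decreasing step
        px_nm = imaging.pixel_size * 1000
        assert abs(first_min_px * px_nm - r0_nm) <= px_nm

    def test_small_radius_rejected(self, imaging):
        with pytest.raises(ValueError):
            airy_psf(imaging, kernel_radius=2)


class TestSimulateImage:
    def test_same_seed_bitwise_identical(self, straight_spec, imaging):
        a = simulate_image([straight_spec], imaging, (140, 470))
        b = simulate_image([straight_spec], imaging, (140, 470))
        assert np.array_equal(a.phalloidin_channel, b.phalloidin_channel)
        assert np.array_equal(a.zdisc_channel, b.zdisc_channel)

    def test_different_seed_differs(self, straight_spec, imaging):
        other = ImagingSpec(pixel_size=imaging.pixel_size, rng_seed=99)
        a = simulate_image([straight_spec], imaging, (140, 470))
        b = simulate_image([straight_spec], other, (140, 470))
        assert not np.array_equal(a.phalloidin_channel, b.phalloidin_channel)

    def test_noiseless_limit_is_blurred_ground_truth(
        self, straight_spec, imaging, ground_truth
    ):
        out = simulate_image([straight_spec], imaging, (140, 470),
                             no_noise=True)
        expected = _convolve_reflect(
            ground_truth.phalloidin_channel, airy_psf(imaging)
        ) * imaging.photon_scale
        assert np.allclose(out.phalloidin_channel, expected)

    def test_noise_is_mean_preserving(self):
        # Poisson and clipped Gaussian labelling noise leave the expected
        # image equal to the blurred ground truth (within Monte-Carlo error)
        spec = MyofibrilSpec(1, 3.2, 1.0, origin=(1.0, 1.6))
        canvas = (64, 110)
        base = ImagingSpec(rng_seed=0)
        expected = simulate_image([spec], base, canvas,
                                  no_noise=True).phalloidin_channel
        n_rep = 1200
        acc = np.zeros(canvas)
        for seed in range(n_rep):
            im = ImagingSpec(rng_seed=seed)
            acc += simulate_image([spec], im, canvas).phalloidin_channel
        mean = acc / n_rep
        sel = expected > 15
        rel = np.abs(mean[sel] - expected[sel]) / expected[sel]
        assert rel.max() < 0.05          # no pixel wildly off
        assert np.mean(rel) < 0.01       # 1% on average

    def test_blur_conserves_total_intensity(self, ground_truth, imaging):
        blurred = _convolve_reflect(ground_truth.phalloidin_channel,
                                    airy_psf(imaging))
        rel = abs(blurred.sum() - ground_truth.phalloidin_channel.sum())
        assert rel / ground_truth.phalloidin_channel.sum() < 1e-3

    def test_manifest_round_trips_ground_truth(self, noisy_image):
        from myomorph import SyntheticImage

        specs, im = SyntheticImage.manifest_specs(noisy_image.to_manifest())
        assert specs == noisy_image.ground_truth
        assert im == noisy_image.imaging
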