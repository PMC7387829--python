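"""Defocus PSF synthesis, sigmoid profiles and annular compositing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import j0

from blurfield.blur import (BlurProfile, DefocusSpec, ZonalSpec,
                            blur_volume_fraction, c20_from_diopters,
                            compose_spatially_varying, convolve_blur,
                            defocus_psf, psf_for_diopters, ring_table,
                            sigmoid_profile, zonal_stimulus)
from blurfield.calibration import arcmin_to_rad

SCALE = 15.0 * 60 / 2160        # display pixel scale, arcmin


class TestC20:
    @pytest.mark.parametrize("M,r,expected", [
        (0.0, 1.0, 0.0),
        (5.0, 1.0, 0.7217),
        (-1.0, 1.0, -0.1443),
        (1.0, 1.0, 1.0 / (4 * np.sqrt(3))),
    ])
    def test_values(self, M, r, expected):
        assert c20_from_diopters(M, r) == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            c20_from_diopters(1.0, 0.0)


class TestSigmoidProfile:
    @pytest.mark.parametrize("E,K,expected", [
        (0.3, 0.0, 0.3),            # K = 0 is the linear profile
        (1.0, 4.0, 1.0),            # normalized at the defocus peak
        (1.0, -0.8, 1.0),
        (0.5, 4.0, 0.1667),
        (0.0, 16.7, 0.0),
    ])
    def test_values(self, E, K, expected):
        assert sigmoid_profile(E, K) == pytest.approx(expected, abs=5e-5)

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_profile(0.5, -1.0)
        with pytest.raises(ValueError):
            sigmoid_profile(0.5, -1.5)

    @given(st.floats(-0.99, 100.0), st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_normalized(self, K, E):
        y = sigmoid_profile(E, K)
        assert -1e-12 <= y <= 1.0 + 1e-12
        assert sigmoid_profile(0.0, K) == 0.0
        assert sigmoid_profile(1.0, K) == pytest.approx(1.0)

    @given(st.floats(-0.99, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_eccentricity(self, K):
        e = np.linspace(0, 1, 101)
        y = sigmoid_profile(e, K)
        assert np.all(np.diff(y) > -1e-12)


class TestBlurVolumeFraction:
    def test_printed_calibration(self):
        """The tested K set maps onto the printed blur-volume fractions."""
        printed = {-0.8: 1.5, -0.53: 1.25, 1.1: 0.75, 4.0: 0.5, 16.7: 0.25}
        for K, frac in printed.items():
            assert blur_volume_fraction(K) == pytest.approx(frac, abs=0.02)

    def test_linear_is_unity(self):
        assert blur_volume_fraction(0.0) == 1.0

    def test_derived_value(self):
        # frozen from adaptive quadrature of the sigmoid integral at K=16.7
        assert blur_volume_fraction(16.7) == pytest.approx(0.244986, abs=1e-5)

    @given(st.floats(-0.99, 100.0))
    @settings(max_examples=150, deadline=None)
    def test_closed_form_matches_quadrature(self, K):
        num, _ = quad(lambda e: sigmoid_profile(e, K), 0.0, 1.0,
                      epsabs=1e-12, epsrel=1e-12)
        assert blur_volume_fraction(K) == pytest.approx(num / 0.5, abs=1e-8)

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError):
            blur_volume_fraction(-1.2)


class TestDefocusPsf:
    def test_unit_energy_and_symmetry(self):
        for M in (0.0, 1.0, 5.0):
            k = psf_for_diopters(M, scale_arcmin=SCALE)
            I = k.intensity
            assert I.sum() == pytest.approx(1.0, abs=1e-9)
            assert I.shape[0] % 2 == 1
            asym = max(np.abs(I - I[::-1, :]).max(),
                       np.abs(I - I[:, ::-1]).max(),
                       np.abs(I - I.T).max())
            assert asym < 1e-6 * I.max()

    def test_zero_defocus_is_diffraction_limited(self):
        k = psf_for_diopters(0.0, scale_arcmin=SCALE)
        c = k.half_width
        assert k.intensity[c, c] == k.intensity.max()
        # any defocus lowers the peak on the same grid
        k1 = psf_for_diopters(1.0, scale_arcmin=SCALE)
        assert k1.intensity.max() < k.intensity.max()

    def test_against_direct_fourier_integral_oracle(self):
        """Radial Hankel quadrature of the pupil integral, sampled on the
        same fine grid and binned to display pixels like the implementation,
        reproduces the FFT kernel peak for M = 1 D within 1%."""
        spec = DefocusSpec(1.0)
        k = psf_for_diopters(1.0, scale_arcmin=SCALE)
        r = spec.pupil_radius_mm
        wl_mm = spec.wavelength_nm * 1e-6
        rr = (np.arange(4096) + 0.5) / 4096 * r
        phi = 2 * np.pi * (spec.c20_um * 1e-3 * np.sqrt(3)
                           * (2 * (rr / r) ** 2 - 1)) / wl_mm
        K = k.intensity.shape[0]
        half_fine = (K * 3) // 2
        th_fine = np.arange(-half_fine, half_fine + 1) * arcmin_to_rad(SCALE) / 3
        grid = np.linspace(0, abs(th_fine[0]) * np.sqrt(2) * 1.01, 4000)
        prof = np.abs([np.trapezoid(rr * j0(2 * np.pi * rr * t / wl_mm)
                                    * np.exp(1j * phi), rr) for t in grid]) ** 2
        TH = np.hypot(th_fine[:, None], th_fine[None, :])
        fine = np.interp(TH, grid, prof)
        oracle = fine.reshape(K, 3, K, 3).sum(axis=(1, 3))
        oracle /= oracle.sum()
        assert k.intensity.max() == pytest.approx(oracle.max(), rel=0.01)

    def test_out_of_range_defocus_rejected(self):
        with pytest.raises(ValueError):
            psf_for_diopters(5.2, scale_arcmin=SCALE)
        with pytest.raises(ValueError):
            psf_for_diopters(-0.5, scale_arcmin=SCALE)

    def test_clipped_support_rejected(self):
        with pytest.raises(ValueError):
            defocus_psf(DefocusSpec(5.0), grid_size=256,
                        pixel_scale_arcmin_=SCALE)


class TestConvolveBlur:
    def test_delta_recovers_kernel(self):
        k = psf_for_diopters(1.0, scale_arcmin=SCALE)
        n = 2 * k.half_width + 41
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = convolve_blur(img, k, image_scale_arcmin=SCALE)
        c, hw = n // 2, k.half_width
        patch = out[c - hw:c + hw + 1, c - hw:c + hw + 1]
        assert np.allclose(patch, k.intensity, atol=1e-12)

    def test_uniform_image_unchanged(self):
        k = psf_for_diopters(2.0, scale_arcmin=SCALE)
        img = np.full((700, 700), 113.0)
        out = convolve_blur(img, k, image_scale_arcmin=SCALE)
        assert np.allclose(out, 113.0, atol=1e-9)

    def test_mean_preserved_on_random_input(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (700, 700))
        k = psf_for_diopters(1.5, scale_arcmin=SCALE)
        out = convolve_blur(img, k, image_scale_arcmin=SCALE)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-3)

    def test_scale_mismatch_rejected(self):
        k = psf_for_diopters(1.0, scale_arcmin=SCALE)
        with pytest.raises(ValueError):
            convolve_blur(np.zeros((512, 512)), k, image_scale_arcmin=SCALE * 2)


class TestCompose:
    def test_zero_peak_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (600, 600))
        profile = BlurProfile(K=4.0, peak_a_D=0.0, extent_deg=7.5)
        scale = 15.0 * 60 / 600
        out, table = compose_spatially_varying(img, profile, scale_arcmin=scale)
        assert np.allclose(out, img)
        assert (table["defocus_D"] == 0).all()

    def test_ring_table_monotone_with_peak_at_edge(self):
        profile = BlurProfile(K=4.0, peak_a_D=5.0, extent_deg=7.5, n_rings=20)
        table = ring_table(profile)
        assert len(table) == 20
        assert table["defocus_D"].iloc[-1] == pytest.approx(5.0)
        assert (table["defocus_D"].diff().dropna() >= 0).all()
        # quantization grid: all on 0.05 D steps
        assert np.allclose(np.round(table["defocus_D"] / 0.05)
                           * 0.05, table["defocus_D"])

    def test_rings_partition_every_pixel_once(self):
        """Each pixel belongs to exactly one annulus by center eccentricity."""
        from blurfield.blur import _eccentricity_map
        scale = 15.0 * 60 / 600
        E = _eccentricity_map((600, 600), scale)
        profile = BlurProfile(K=1.1, peak_a_D=2.0)
        idx = np.clip(np.ceil(E / profile.ring_width_deg).astype(int), 1, 20)
        counts = np.zeros((600, 600), dtype=int)
        for i in range(1, 21):
            counts += (idx == i)
        assert (counts == 1).all()

    def test_constant_profile_equals_global_convolution(self):
        """All rings at one level must reduce to a single convolution away
        from the outer boundary."""
        class ConstantProfile(BlurProfile):
            def ring_defocus_D(self, reference="outer"):
                return np.full(self.n_rings, 1.0)

        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (600, 600))
        scale = 15.0 * 60 / 600
        profile = ConstantProfile(K=0.0, peak_a_D=1.0)
        out, _ = compose_spatially_varying(img, profile, scale_arcmin=scale)
        k = psf_for_diopters(1.0, scale_arcmin=scale)
        ref = convolve_blur(img, k, image_scale_arcmin=scale)
        assert np.allclose(out, ref, atol=1e-9)

    def test_peak_beyond_psf_set_rejected(self):
        with pytest.raises(ValueError):
            BlurProfile(K=4.0, peak_a_D=5.5).__class__  # construction is fine
            compose_spatially_varying(np.zeros((600, 600)),
                                      BlurProfile(K=4.0, peak_a_D=5.5),
                                      scale_arcmin=15.0 * 60 / 600)

    def test_extent_beyond_image_rejected(self):
        with pytest.raises(ValueError):
            compose_spatially_varying(np.zeros((100, 100)),
                                      BlurProfile(K=0.0, peak_a_D=1.0,
                                                  extent_deg=7.5),
                                      scale_arcmin=1.0)


class TestZonal:
    SCALE600 = 15.0 * 60 / 600

    def test_annulus_geometry(self):
        zone = ZonalSpec(outer_ecc_deg=7.5, blur_D=1.0)
        assert zone.inner_ecc_deg == pytest.approx(6.0)

    def test_sharp_annulus_on_background(self):
        from blurfield.blur import _eccentricity_map
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (600, 600))
        zone = ZonalSpec(outer_ecc_deg=3.0, blur_D=0.0)
        out = zonal_stimulus(img, zone, background_level=40.0,
                             scale_arcmin=self.SCALE600)
        E = _eccentricity_map(img.shape, self.SCALE600)
        ann = (E > 1.5) & (E <= 3.0)
        assert np.array_equal(out[ann], img[ann])
        assert np.all(out[~ann] == 40.0)

    def test_five_zones_union_is_the_disk(self):
        """The five zonal annuli together cover exactly the 7.5 deg disk."""
        from blurfield.blur import _eccentricity_map
        E = _eccentricity_map((600, 600), self.SCALE600)
        covered = np.zeros((600, 600), dtype=int)
        for outer in (1.5, 3.0, 4.5, 6.0, 7.5):
            covered += ((E > outer - 1.5) & (E <= outer))
        disk = E <= 7.5
        assert np.array_equal(covered.astype(bool), disk)
        assert covered.max() == 1

    def test_zone_outside_field_rejected(self):
        with pytest.raises(ValueError):
            zonal_stimulus(np.zeros((100, 100)),
                           ZonalSpec(outer_ecc_deg=7.5, blur_D=1.0),
                           background_level=0.0, scale_arcmin=1.0)
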