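"""SLM pattern generation and the effective device model."""

import numpy as np
import pytest

from slmscat import (
    PF_STEP,
    FresnelParams,
    band_mask,
    directional_band,
    fork_pattern,
    fresnel_pattern,
    grating_pattern,
    highpass,
    identity_transmission,
    lowpass,
    to_transmission,
    uniform_pattern,
)
from slmscat.optics import ComplexField, Plane, to_image
from slmscat.patterns import defocus_null_power


class TestBandMasks:
    def test_rejects_inverted_band(self, grid256):
        with pytest.raises(ValueError):
            band_mask(grid256, 0.5, 0.2)

    def test_zero_cutoff_highpass_is_identity(self, grid256):
        p = highpass(grid256, 0.0)
        assert np.all(p.levels == 255)

    def test_beyond_corner_highpass_blocks_all(self, grid256):
        p = highpass(grid256, grid256.nyquist * np.sqrt(2) * 1.01)
        assert np.all(p.levels == 0)

    @pytest.mark.parametrize("nu_c", [0.1, 0.25, 0.4])
    def test_blocked_pixel_count(self, grid256, nu_c):
        """Blocked pixels ~ disc area, within a perimeter's worth of pixels."""
        p = highpass(grid256, nu_c)
        blocked = int(np.sum(p.levels == 0))
        # independent oracle: brute-force lattice points inside the disc
        r_px = nu_c / grid256.freq_step
        idx = np.arange(256) - 128
        ii, jj = np.meshgrid(idx, idx)
        oracle = int(np.sum(np.hypot(ii, jj) < r_px))
        assert blocked == oracle
        assert abs(blocked - np.pi * r_px**2) <= 2 * np.pi * r_px + 8

    def test_complementarity(self, grid256):
        nu_c = 0.22
        total = highpass(grid256, nu_c).levels.astype(int) + lowpass(
            grid256, nu_c
        ).levels.astype(int)
        assert np.all(total == 255)


class TestDirectionalBand:
    def test_half_turn_symmetry(self, grid256):
        a = directional_band(grid256, 32.0, 0.1).levels
        b = directional_band(grid256, 212.0, 0.1).levels
        assert np.array_equal(a, b)

    def test_dc_always_passed(self, grid256):
        for theta in (-90.0, -37.5, 0.0, 64.0):
            p = directional_band(grid256, theta, 0.05)
            assert p.levels[128, 128] == 255

    def test_huge_thickness_passes_everything(self, grid256):
        thickness = 2.1 * grid256.nyquist * np.sqrt(2)
        p = directional_band(grid256, 17.0, thickness)
        assert np.all(p.levels == 255)

    def test_rejects_nonpositive_thickness(self, grid256):
        with pytest.raises(ValueError):
            directional_band(grid256, 0.0, 0.0)


class TestFresnel:
    def test_zero_power_is_flat(self, grid256):
        p = fresnel_pattern(FresnelParams(40, 0.0), grid256)
        assert np.all(p.levels == 0)

    def test_power_quantization_step(self):
        assert PF_STEP == 1.0 / 256.0
        assert PF_STEP == pytest.approx(0.004, abs=1e-4)

    @pytest.mark.parametrize("pf", [0.1, 0.303, -0.517])
    def test_encoded_power_is_quantized(self, pf):
        q = FresnelParams(60, pf).quantized_pf
        assert q == pytest.approx(round(pf * 256) / 256, abs=0)
        assert abs(q - pf) <= PF_STEP / 2

    def test_zone_undersampling_rejected(self, grid256):
        with pytest.raises(ValueError, match="undersampling"):
            fresnel_pattern(FresnelParams(120, 10.0, kappa=50.0), grid256)

    def test_pattern_zero_outside_radius(self, grid256):
        p = fresnel_pattern(FresnelParams(20, 0.1), grid256)
        r = grid256.freq_radius()
        assert np.all(p.levels[r > 20 * grid256.freq_step] == 0)

    def test_null_power_is_device_representable(self, grid512):
        pf = defocus_null_power(grid512)
        assert pf == pytest.approx(round(pf * 256) / 256, abs=0)


class TestFourierManipulations:
    def test_grating_shifts_image_by_whole_pixels(self, grid256):
        """A grating of q cycles across the pupil displaces the image q px."""
        q = 7
        n = 256
        impulse = np.zeros((n, n), dtype=complex)
        impulse[128, 128] = 1.0
        pupil = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(impulse), norm="ortho"))
        t = to_transmission(grating_pattern(grid256, q, angle_deg=0.0))
        shifted = to_image(
            ComplexField(t.values * pupil, Plane.PUPIL, grid256)
        ).values
        peak = np.unravel_index(np.abs(shifted).argmax(), shifted.shape)
        assert peak[0] == 128
        assert (peak[1] - 128) % n in (q, n - q)

    def test_fork_nulls_on_axis(self, grid256):
        from slmscat.optics import aperture_mask

        t = to_transmission(fork_pattern(grid256, charge=1))
        ap = aperture_mask(grid256).astype(complex)
        image = to_image(ComplexField(t.values * ap, Plane.PUPIL, grid256)).values
        center = np.abs(image[128, 128]) ** 2
        assert center < 1e-3 * (np.abs(image) ** 2).max()

    def test_trivial_fork_is_uniform(self, grid256):
        p = fork_pattern(grid256, charge=0, cycles=0.0)
        assert np.unique(p.levels).size == 1


class TestDeviceModel:
    def test_amplitude_endpoints(self, grid64):
        t0 = to_transmission(uniform_pattern(grid64, 0))
        t255 = to_transmission(uniform_pattern(grid64, 255))
        assert np.all(t0.values == 0.0)
        assert np.all(t255.values == 1.0)

    def test_phase_level_128_is_minus_one(self, grid64):
        t = to_transmission(uniform_pattern(grid64, 128, mode="phase"))
        assert np.allclose(t.values, -1.0, atol=1e-12)

    @pytest.mark.parametrize("kind", ["fresnel", "grating", "amplitude"])
    def test_transmissions_are_passive(self, grid256, kind):
        if kind == "fresnel":
            pattern = fresnel_pattern(FresnelParams(40, 0.05), grid256)
        elif kind == "grating":
            pattern = grating_pattern(grid256, 11.0, 30.0)
        else:
            pattern = band_mask(grid256, 0.05, 0.2)
        assert np.abs(to_transmission(pattern).values).max() <= 1.0 + 1e-12

    def test_identity_transmission_is_all_pass(self, grid64):
        t = identity_transmission(grid64)
        assert np.all(t.values == 1.0)
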