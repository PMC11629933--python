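"""Forward imaging model and acquisition schedules."""

import numpy as np
import pytest

from slmscat import (
    CameraModel,
    FresnelParams,
    InsufficientDefocusError,
    Scene,
    acquire_stack,
    alternating_stack,
    form_frame,
    fresnel_pattern,
    highpass,
    identity_transmission,
    scattered_pupil,
    to_transmission,
)
from slmscat.imaging import ForwardModel
from slmscat.patterns import defocus_null_power
from slmscat.scenes import BackgroundModel, Scatterer, make_particle_scene


def single_particle_scene(grid, s=0.05, phase=0.0, speckle=0.0, x=None, y=None):
    bg = BackgroundModel(speckle_rms=speckle, seed=0)
    c = grid.center
    sc = Scatterer(x=c if x is None else x, y=c if y is None else y,
                   amplitude_s=s, phase_phi=phase)
    return Scene([sc], bg, grid)


class TestScatteredField:
    def test_empty_scene_is_dark(self, grid256):
        scene = Scene([], BackgroundModel(seed=0), grid256)
        assert np.all(scattered_pupil(scene).values == 0.0)

    def test_lateral_shift_moves_image_spot(self, grid256):
        """Pupil phase ramp from a displacement moves the spot by exactly
        that displacement (Fourier shift theorem oracle)."""
        from slmscat.optics import ComplexField, Plane, to_image

        scene = single_particle_scene(grid256)
        for dx_px in (7, 23):
            field = scattered_pupil(scene, shift_x=dx_px * grid256.pixel_size)
            img = np.abs(to_image(ComplexField(field.values, Plane.PUPIL, grid256)).values) ** 2
            peak = np.unravel_index(img.argmax(), img.shape)
            assert peak == (128, 128 + dx_px)


class TestFrameFormation:
    def test_background_only_frame_is_scaled_envelope(self, grid256):
        scene = Scene([], BackgroundModel(speckle_rms=0.0, seed=0), grid256)
        frame = form_frame(scene, identity_transmission(grid256), noise=False)
        from slmscat.optics import aperture_mask
        from slmscat.scenes import make_background
        from slmscat.optics import to_pupil, to_image, ComplexField, Plane

        env = make_background(BackgroundModel(speckle_rms=0.0, seed=0), grid256)
        pupil = to_pupil(env).values
        pupil[~aperture_mask(grid256)] = 0.0
        expected = np.abs(to_image(ComplexField(pupil, Plane.PUPIL, grid256)).values) ** 2
        expected *= frame.pixels.max() / expected.max()
        assert np.allclose(frame.pixels, expected, atol=1e-6 * frame.pixels.max())

    def test_exposure_rule(self, scene40):
        """Noiseless maximum pixel sits at 85-90% of full well."""
        frame = form_frame(scene40, identity_transmission(scene40.grid), noise=False)
        camera = CameraModel()
        frac = frame.pixels.max() / camera.full_well
        assert 0.85 <= frac <= 0.90

    def test_blocked_frame_flagged_not_crashed(self, grid256):
        scene = single_particle_scene(grid256)
        # cutoff beyond the aperture blocks everything
        t = to_transmission(highpass(grid256, grid256.nu_na * 1.2))
        frame = form_frame(scene, t, noise=False)
        assert np.all(frame.pixels == 0.0)
        assert "warning" in frame.metadata

    def test_shot_noise_variance_tracks_mean(self, grid256):
        """In a flat bright region the count variance approximates the mean."""
        scene = Scene([], BackgroundModel(speckle_rms=0.0, envelope_width=80.0, seed=0), grid256)
        frame = form_frame(scene, identity_transmission(grid256), noise=True, seed=7)
        region = frame.pixels[118:138, 118:138]
        assert region.var() == pytest.approx(region.mean(), rel=0.15)

    def test_amplitude_filter_never_gains_energy(self, grid256, scene40):
        model = ForwardModel(scene40)
        full = model.intensity(identity_transmission(scene40.grid)).sum()
        for nu_c in (0.05, 0.15, 0.3):
            filt = model.intensity(to_transmission(highpass(scene40.grid, nu_c))).sum()
            assert filt <= full * (1 + 1e-12)

    def test_interference_sign(self, grid256):
        """A scatterer in phase with the reference brightens the image; in
        antiphase it darkens it, with equal |C| at small amplitude."""
        contrasts = {}
        for phase in (0.0, np.pi):
            scene = single_particle_scene(grid256, s=1e-4, phase=phase)
            model = ForwardModel(scene)
            with_p = model.intensity(identity_transmission(grid256))
            without = model.intensity(identity_transmission(grid256), include_particles=False)
            c = grid256.n // 2
            contrasts[phase] = with_p[c, c] / without[c, c] - 1.0
        assert contrasts[0.0] > 0 > contrasts[np.pi]
        assert abs(contrasts[0.0]) == pytest.approx(abs(contrasts[np.pi]), abs=1e-6)


class TestAcquisition:
    def test_static_noiseless_stack_is_constant(self, grid256):
        scene = single_particle_scene(grid256, speckle=0.03)
        stack = acquire_stack(scene, identity_transmission(grid256), 4,
                              lateral_step=0.0, noise=False)
        assert np.array_equal(stack.pixels[0], stack.pixels[3])

    def test_long_stack_metadata(self, grid64):
        scene = single_particle_scene(grid64, x=3.0, y=3.0)
        stack = acquire_stack(scene, identity_transmission(grid64), 300,
                              lateral_step=0.0, noise=False)
        assert len(stack) == 300
        assert len(stack.metadata) == 300
        assert stack.metadata[299]["frame_index"] == 299

    def test_wrap_flagged(self, grid64):
        scene = single_particle_scene(grid64, x=5.0, y=3.0)
        stack = acquire_stack(scene, identity_transmission(grid64), 3,
                              lateral_step=2.0, noise=False)
        assert stack.metadata[2].get("wrapped", False)

    def test_noise_reproducible_under_seed(self, grid256):
        scene = single_particle_scene(grid256)
        a = acquire_stack(scene, identity_transmission(grid256), 2, seed=5, noise=True)
        b = acquire_stack(scene, identity_transmission(grid256), 2, seed=5, noise=True)
        assert np.array_equal(a.pixels, b.pixels)

    def test_identity_pattern_leaves_frames_bit_identical(self, grid256):
        """Displaying the all-pass pattern is indistinguishable from no SLM."""
        from slmscat import uniform_pattern

        scene = single_particle_scene(grid256, speckle=0.03)
        direct = form_frame(scene, identity_transmission(grid256), noise=False)
        via_pattern = form_frame(
            scene, to_transmission(uniform_pattern(grid256, 255)), noise=False
        )
        assert np.array_equal(direct.pixels, via_pattern.pixels)


class TestAlternatingSchedule:
    def make_pattern(self, grid, pf=None):
        rf = int(np.ceil(grid.nu_na / grid.freq_step)) + 2
        return fresnel_pattern(
            FresnelParams(rf, defocus_null_power(grid) if pf is None else pf), grid
        )

    def test_pair_labels(self, grid512):
        scene = make_particle_scene([40.0], 1, 3.0, 1, grid512)
        stack = alternating_stack(
            scene, identity_transmission(grid512), self.make_pattern(grid512),
            n_pairs=1, noise=False,
        )
        assert len(stack) == 2
        assert [m["pattern"] for m in stack.metadata] == ["focused", "defocused"]

    def test_focused_frames_match_plain_acquisition(self, grid512):
        scene = make_particle_scene([40.0], 1, 3.0, 1, grid512)
        stack = alternating_stack(
            scene, identity_transmission(grid512), self.make_pattern(grid512),
            n_pairs=1, noise=False,
        )
        plain = form_frame(scene, identity_transmission(grid512), noise=False)
        assert np.allclose(stack.pixels[0], plain.pixels, rtol=1e-12)

    def test_weak_lens_raises_insufficient_defocus(self, grid512):
        scene = make_particle_scene([40.0], 1, 3.0, 1, grid512)
        with pytest.raises(InsufficientDefocusError, match="residual"):
            alternating_stack(
                scene, identity_transmission(grid512),
                self.make_pattern(grid512, pf=1.0 / 256.0), n_pairs=1, noise=False,
            )
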