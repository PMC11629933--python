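"""Measurement pipeline: normalisation, detection, fitting, sweeps."""

import numpy as np
import pytest

from slmscat import (
    AcquisitionConfig,
    FrameStack,
    acquire_stack,
    bootstrap_ci,
    contrast,
    detect_particles,
    displaced_median_background,
    divide_background,
    fit_profile_sinc,
    fit_sine,
    highpass_sweep,
    identity_transmission,
    median_normalize,
    optimal_cutoff,
)
from slmscat.analysis import SweepResult
from slmscat.imaging import Frame
from slmscat.scenes import BackgroundModel, Scatterer, Scene, make_particle_scene
import pandas as pd


class TestMedianNormalize:
    def test_constant_stack_maps_to_ones(self, grid64):
        stack = FrameStack(np.full((4, 64, 64), 7.0), grid64)
        norm = median_normalize(stack)
        assert np.all(norm.pixels == 1.0)

    def test_median_of_normalized_stack_is_one(self, grid256):
        scene = make_particle_scene([40.0], 3, 3.0, 1, grid256)
        stack = acquire_stack(scene, identity_transmission(grid256), 5,
                              lateral_step=2.0, noise=False)
        norm = median_normalize(stack)
        med = np.median(norm.pixels, axis=0)
        assert np.allclose(med, 1.0, atol=1e-12)

    def test_needs_three_frames(self, grid64):
        with pytest.raises(ValueError, match="3 frames"):
            median_normalize(FrameStack(np.ones((2, 64, 64)), grid64))

    def test_zero_median_pixel_named(self, grid64):
        pixels = np.ones((3, 64, 64))
        pixels[:, 5, 9] = 0.0
        with pytest.raises(ValueError, match=r"\(5, 9\)"):
            median_normalize(FrameStack(pixels, grid64))


class TestDisplacedMedianBackground:
    def test_particles_vanish_from_median(self, grid256):
        """The median of a displaced stack shows no particle signature at
        the planted positions beyond 3x the pixel noise scale."""
        bg_model = BackgroundModel(seed=3)
        scene = make_particle_scene([40.0], 3, 3.0, 3, grid256, background=bg_model)
        stack = acquire_stack(scene, identity_transmission(grid256), 24,
                              lateral_step=2.0, noise=True, seed=3)
        background = displaced_median_background(stack)
        empty = Scene([], bg_model, grid256)
        oracle = acquire_stack(empty, identity_transmission(grid256), 24,
                               lateral_step=2.0, noise=True, seed=3)
        oracle_med = np.median(oracle.pixels, axis=0)
        support = oracle_med > 0.05 * oracle_med.max()
        # exposure scaling differs between the stacks: compare as a ratio
        ratio = np.where(support, background.pixels / np.where(support, oracle_med, 1.0), 1.0)
        ratio /= np.median(ratio[support])
        noise_rms = float(np.std(ratio[support]))
        for sc in scene.scatterers:
            i = int(round(sc.y / grid256.pixel_size))
            j = int(round(sc.x / grid256.pixel_size))
            dip = np.abs(ratio[i - 1 : i + 2, j - 1 : j + 2] - 1.0).max()
            assert dip < 3.0 * noise_rms

    def test_single_frame_warns(self, grid64):
        stack = FrameStack(np.ones((1, 64, 64)), grid64)
        with pytest.warns(UserWarning, match="single-frame"):
            displaced_median_background(stack)

    def test_zero_step_warns(self, grid64):
        stack = FrameStack(np.ones((4, 64, 64)), grid64,
                           [{"lateral_offset": 0.0} for _ in range(4)])
        with pytest.warns(UserWarning, match="displacement"):
            displaced_median_background(stack)


class TestDivideBackground:
    def test_equal_frames_give_ones(self, grid64):
        f = Frame(np.full((64, 64), 5.0), grid64)
        out = divide_background(f, f)
        assert np.all(out.pixels == 1.0)

    def test_zero_pixels_rejected(self, grid64):
        f = Frame(np.ones((64, 64)), grid64)
        d = Frame(np.zeros((64, 64)), grid64)
        with pytest.raises(ValueError, match="non-positive"):
            divide_background(f, d)


class TestContrast:
    @pytest.mark.parametrize(
        "Is, Ib, expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (0.99, 1.0, -0.01)]
    )
    def test_formula(self, Is, Ib, expected):
        assert contrast(Is, Ib) == pytest.approx(expected, abs=1e-15)

    def test_rejects_dark_background(self):
        with pytest.raises(ValueError):
            contrast(1.0, 0.0)


class TestDetection:
    def _normalized(self, scene, noise, seed=0):
        stack = acquire_stack(scene, identity_transmission(scene.grid), 8,
                              lateral_step=2.0, noise=noise, seed=seed)
        med = np.median(stack.pixels, axis=0)
        support = med > 0.01 * med.max()
        norm = np.where(support, stack.pixels[0] / np.where(support, med, 1.0), 1.0)
        return Frame(norm, scene.grid), support, med

    def test_planted_particle_recovered_within_one_pixel(self, grid256):
        scene = make_particle_scene([40.0], 1, 3.0, 5, grid256)
        frame, support, med = self._normalized(scene, noise=True, seed=5)
        detections = detect_particles(frame, support_mask=support, counts_map=med)
        sc = scene.scatterers[0]
        hits = [d for d in detections
                if np.hypot(d[0] - sc.x, d[1] - sc.y) <= grid256.pixel_size]
        assert hits

    @pytest.mark.parametrize("seed", range(20))
    def test_particle_free_frame_yields_nothing(self, grid256, seed):
        empty = Scene([], BackgroundModel(seed=seed), grid256)
        frame, support, med = self._normalized(empty, noise=True, seed=seed)
        assert detect_particles(frame, support_mask=support, counts_map=med) == []

    def test_unresolved_pair_collapses_to_one(self, grid256):
        c = grid256.center
        bg = BackgroundModel(speckle_rms=0.0, seed=0)
        pair = Scene(
            [Scatterer(x=c - 0.1, y=c, amplitude_s=0.05),
             Scatterer(x=c + 0.1, y=c, amplitude_s=0.05)],
            bg, grid256,
        )
        frame, support, med = self._normalized(pair, noise=False)
        assert len(detect_particles(frame, support_mask=support, counts_map=med)) == 1


class TestSincFit:
    def _frame_from_profile(self, grid, y):
        pixels = np.ones((grid.n, grid.n))
        pixels[grid.n // 2, :] = y
        return Frame(pixels, grid)

    def test_self_consistency(self, grid256):
        x = (np.arange(256) - 128) * grid256.pixel_size
        y = 1.0 + 0.08 * np.sinc(x / 0.61)
        frame = self._frame_from_profile(grid256, y)
        fit = fit_profile_sinc(frame, (grid256.center, grid256.center))
        assert fit.amplitude_A == pytest.approx(0.08, abs=1e-6)
        assert fit.baseline_Ib == pytest.approx(1.0, abs=1e-6)
        assert fit.width_w == pytest.approx(0.61, abs=1e-4)
        assert fit.Is == pytest.approx(1.08, abs=1e-6)

    def test_flat_profile_gives_zero_amplitude(self, grid256):
        frame = self._frame_from_profile(grid256, np.ones(256))
        fit = fit_profile_sinc(frame, (grid256.center, grid256.center))
        assert abs(fit.amplitude_A) < 1e-10

    def test_dark_particle_keeps_sign(self, grid256):
        x = (np.arange(256) - 128) * grid256.pixel_size
        y = 1.0 - 0.05 * np.sinc(x / 0.61)
        frame = self._frame_from_profile(grid256, y)
        fit = fit_profile_sinc(frame, (grid256.center, grid256.center))
        assert fit.amplitude_A == pytest.approx(-0.05, abs=1e-6)
        assert contrast(fit.Is, fit.baseline_Ib) < 0

    def test_profile_outside_image_rejected(self, grid256):
        frame = self._frame_from_profile(grid256, np.ones(256))
        with pytest.raises(ValueError, match="outside"):
            fit_profile_sinc(frame, (0.3, 0.3))


class TestBootstrap:
    def test_ci_width_shrinks_as_root_n(self, rng):
        """Quadrupling the sample roughly halves the CI width."""
        widths = {}
        for n in (40, 160):
            values = rng.normal(0.5, 0.1, size=n)
            lo, hi = bootstrap_ci(values, n_boot=2000, seed=1)
            widths[n] = hi - lo
        ratio = widths[40] / widths[160]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_ci_brackets_mean(self, rng):
        values = rng.normal(size=30)
        lo, hi = bootstrap_ci(values, seed=0)
        assert lo <= values.mean() <= hi


class TestOptimalCutoff:
    @staticmethod
    def _sweep(values, means):
        n = len(values)
        return SweepResult(
            parameter="nu_c",
            values=np.asarray(values, dtype=float),
            mean_contrast=np.asarray(means, dtype=float),
            ci95_low=np.asarray(means, dtype=float) - 0.01,
            ci95_high=np.asarray(means, dtype=float) + 0.01,
            per_particle=pd.DataFrame(),
        )

    def test_monotone_decreasing_sweep_reported_honestly(self):
        sweep = self._sweep([0.0, 0.1, 0.2, 0.3], [0.10, 0.08, 0.05, 0.02])
        nu, period, enh = optimal_cutoff(sweep)
        assert nu == 0.1
        assert period == pytest.approx(10.0)
        assert enh <= 1.0

    def test_tie_breaks_to_smallest_cutoff(self):
        sweep = self._sweep([0.0, 0.1, 0.2], [0.1, 0.5, 0.5])
        nu, _, _ = optimal_cutoff(sweep)
        assert nu == 0.1

    def test_missing_values_skipped(self):
        sweep = self._sweep([0.0, 0.1, 0.2], [0.1, np.nan, 0.4])
        nu, _, enh = optimal_cutoff(sweep)
        assert nu == 0.2
        assert enh == pytest.approx(4.0)

    def test_nonpositive_baseline_rejected(self):
        sweep = self._sweep([0.0, 0.1], [-0.2, 0.5])
        with pytest.raises(ValueError, match="baseline"):
            optimal_cutoff(sweep)

    def test_baseline_entry_equals_unfiltered_pipeline(self, grid256):
        """Cutoff 0 runs the identity filter: bit-equal to a direct
        unfiltered measurement."""
        scene = make_particle_scene([40.0], 3, 3.0, 7, grid256)
        config = AcquisitionConfig(n_frames=6, noise=False, seed=7)
        sweep_a = highpass_sweep(scene, [0.0, 0.2], config)
        sweep_b = highpass_sweep(scene, [0.0, 0.25], config)
        assert sweep_a.mean_contrast[0] == sweep_b.mean_contrast[0]


class TestSineFit:
    def test_free_period_recovery(self):
        th = np.arange(-90, 91, 5.0)
        y = 0.4 + 0.3 * np.sin(2 * np.pi * (th - 12.0) / 77.0)
        fit = fit_sine(th, y)
        assert fit.period == pytest.approx(77.0, rel=0.01)

    def test_rectified_cosine_period(self):
        """|cos 2θ| has a 90° fundamental; the pure-sine LS fit lands within
        2° (it is biased slightly low by the rectified waveform's shape)."""
        th = np.arange(-90, 91, 5.0)
        fit = fit_sine(th, np.abs(np.cos(2 * np.deg2rad(th))))
        assert fit.period == pytest.approx(90.0, abs=2.0)

    def test_signed_cosine_period(self):
        th = np.arange(-90, 91, 5.0)
        fit = fit_sine(th, np.cos(2 * np.deg2rad(th)))
        assert fit.period == pytest.approx(180.0, abs=2.0)
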