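"""Forward imaging model: scene + pupil transmission + defocus -> camera frames.

The reference field is the coverslip-reflection background itself (common-path
interferometric geometry): the camera records

    I = |to_image(T · (P_background + P_scattered))|²

with ``T`` the SLM transmission applied at the pupil.  Frames are
auto-exposed so the noiseless maximum pixel sits at a fixed fraction of the
detector full-well capacity, then optionally degraded with Poisson shot noise
and Gaussian read noise.

Scattered fields are normalised so that an isotropic scatterer of amplitude
``s`` at focus interferes with the local reference at relative amplitude
``s`` — i.e. the unfiltered interference contrast is ``2·s·cos(φ) + s²``
independent of where in the envelope the particle sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import (
    ComplexField,
    GridSpec,
    Plane,
    aperture_mask,
    defocus_phase,
    psf_peak_amplitude,
    to_pupil,
)
from .patterns import SLMPattern, Transmission, to_transmission
from .scenes import Scene, make_background

__all__ = [
    "CameraModel",
    "Frame",
    "FrameStack",
    "InsufficientDefocusError",
    "scattered_pupil",
    "form_frame",
    "acquire_stack",
    "alternating_stack",
    "ForwardModel",
]


@dataclass(frozen=True)
class CameraModel:
    """Detector model: full well, read noise and the auto-exposure rule."""

    full_well: float = 10000.0  # electrons
    read_noise: float = 5.0  # electrons RMS
    exposure_target_fraction: float = 0.875
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not 0.0 < self.exposure_target_fraction < 1.0:
            raise ValueError("exposure_target_fraction must lie in (0, 1)")

    @property
    def max_count(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class Frame:
    """A single intensity image in detector counts, with acquisition metadata."""

    pixels: np.ndarray
    grid: GridSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.grid.n, self.grid.n):
            raise ValueError("frame shape does not match grid")
        if self.pixels.min() < 0:
            raise ValueError("intensity frames must be non-negative")


@dataclass
class FrameStack:
    """A stack of frames sharing one grid, with per-frame metadata."""

    pixels: np.ndarray  # (n_frames, n, n)
    grid: GridSpec
    metadata: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[1:] != (self.grid.n, self.grid.n):
            raise ValueError("stack shape must be (n_frames, n, n) matching the grid")
        if not self.metadata:
            self.metadata = [{} for _ in range(self.pixels.shape[0])]
        if len(self.metadata) != self.pixels.shape[0]:
            raise ValueError("one metadata record per frame required")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def frame(self, k: int) -> Frame:
        return Frame(self.pixels[k], self.grid, dict(self.metadata[k]))


class InsufficientDefocusError(RuntimeError):
    """The Fresnel defocus left too much residual particle contrast."""

    def __init__(self, residual: float, limit: float):
        self.residual = residual
        self.limit = limit
        super().__init__(
            f"insufficient defocus: residual particle contrast is "
            f"{residual:.3f} of focused (limit {limit:.2f})"
        )


# ---------------------------------------------------------------------------
# Scattered field
# ---------------------------------------------------------------------------


def _envelope_at(scene: Scene, x: float, y: float) -> float:
    bg = scene.background
    c = scene.grid.center
    return bg.envelope_amplitude * float(
        np.exp(-((x - c) ** 2 + (y - c) ** 2) / bg.envelope_width**2)
    )


def scattered_pupil(
    scene: Scene,
    grid: GridSpec | None = None,
    defocus_z: float = 0.0,
    shift_x: float = 0.0,
    shift_y: float = 0.0,
) -> ComplexField:
    """Coherent sum of all scatterers' pupil-plane fields.

    Each scatterer contributes an aperture-limited plane-wave ramp for its
    position, a paraxial defocus phasor for ``defocus_z`` plus its own axial
    offset, the local illumination envelope, and (for rods) the two-mode
    angular weight.  ``shift_x`` laterally displaces every scatterer, used by
    the stage-translation acquisition protocol.
    """
    if grid is None:
        grid = scene.grid
    nx, ny = grid.freq_grids()
    ap = aperture_mask(grid)
    h_peak = psf_peak_amplitude(grid)
    total = np.zeros((grid.n, grid.n), dtype=complex)
    c = grid.center
    azimuth = np.arctan2(ny, nx)
    for s in scene.scatterers:
        x = (s.x + shift_x) % grid.extent
        y = (s.y + shift_y) % grid.extent
        ramp = np.exp(-2j * np.pi * (nx * (x - c) + ny * (y - c)))
        contrib = (s.amplitude_s * np.exp(1j * s.phase_phi) * _envelope_at(scene, x, y) / h_peak) * ramp
        if s.anisotropy is not None:
            a = s.anisotropy
            alpha = np.deg2rad(a.axis_angle_alpha)
            weight = np.abs(np.cos(azimuth - alpha)) * (a.s_long / s.amplitude_s) + np.exp(
                1j * a.mode_phase_offset
            ) * np.abs(np.sin(azimuth - alpha)) * (a.s_trans / s.amplitude_s)
            contrib = contrib * weight
        z_total = defocus_z + s.z
        if z_total != 0.0:
            contrib = contrib * defocus_phase(grid, z_total)
        total += np.where(ap, contrib, 0.0)
    return ComplexField(total, Plane.PUPIL, grid)


# ---------------------------------------------------------------------------
# Frame formation
# ---------------------------------------------------------------------------


def _expose(
    intensity: np.ndarray,
    camera: CameraModel,
    noise: bool,
    rng: np.random.Generator | None,
    scale: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Auto-expose to the full-well target, then apply the noise model.

    ``scale`` fixes the exposure externally: a stack is acquired with one
    exposure time set at its start, not re-metered every frame.
    """
    meta: dict = {}
    if scale is None:
        peak = float(intensity.max())
        if peak <= 0.0:
            meta["warning"] = "fully blocked: zero intensity frame"
            return np.zeros_like(intensity), meta
        scale = camera.exposure_target_fraction * camera.full_well / peak
    elif scale <= 0.0:
        meta["warning"] = "fully blocked: zero intensity frame"
        return np.zeros_like(intensity), meta
    counts = intensity * scale
    meta["exposure_scale"] = scale
    if noise:
        if rng is None:
            raise ValueError("noise requires a random generator")
        counts = rng.poisson(counts).astype(float)
        counts += rng.normal(0.0, camera.read_noise, size=counts.shape)
        counts = np.clip(counts, 0.0, camera.max_count)
    return counts, meta


class ForwardModel:
    """Renders frames of one scene efficiently for many transmissions.

    The background pupil and the per-displacement scattered pupils are
    computed once and cached; rendering a frame for a new SLM pattern is then
    a single masked inverse FFT.  Parameter sweeps rely on this.
    """

    def __init__(self, scene: Scene, camera: CameraModel | None = None):
        self.scene = scene
        self.grid = scene.grid
        self.camera = camera or CameraModel()
        # the background also passes through the objective pupil
        ap = aperture_mask(scene.grid)
        self._bg_pupil = np.where(
            ap, to_pupil(make_background(scene.background, scene.grid)).values, 0.0
        )
        self._scat_cache: dict[float, np.ndarray] = {}

    def scattered(self, shift_x: float = 0.0, shift_y: float = 0.0) -> np.ndarray:
        key = (round(shift_x, 9), round(shift_y, 9))
        if key not in self._scat_cache:
            self._scat_cache[key] = scattered_pupil(
                self.scene, self.grid, shift_x=shift_x, shift_y=shift_y
            ).values
        return self._scat_cache[key]

    def intensity(
        self,
        transmission: Transmission,
        shift_x: float = 0.0,
        defocus_z: float = 0.0,
        include_particles: bool = True,
        shift_y: float = 0.0,
    ) -> np.ndarray:
        """Noiseless intensity before exposure scaling.

        ``defocus_z`` models a stage translation: reference and scattered
        fields both acquire the paraxial defocus phase.
        """
        pupil = self._bg_pupil
        if include_particles:
            pupil = pupil + self.scattered(shift_x, shift_y)
        if defocus_z != 0.0:
            pupil = pupil * defocus_phase(self.grid, defocus_z)
        field = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(transmission.values * pupil), norm="ortho")
        )
        return np.abs(field) ** 2

    def exposure_scale(
        self,
        transmission: Transmission,
        shift_x: float = 0.0,
        defocus_z: float = 0.0,
        shift_y: float = 0.0,
    ) -> float:
        """Exposure metering: counts per intensity unit putting the current
        noiseless maximum pixel at the full-well target; 0 if dark."""
        peak = float(
            self.intensity(transmission, shift_x, defocus_z, shift_y=shift_y).max()
        )
        if peak <= 0.0:
            return 0.0
        return self.camera.exposure_target_fraction * self.camera.full_well / peak

    def frame(
        self,
        transmission: Transmission,
        shift_x: float = 0.0,
        defocus_z: float = 0.0,
        noise: bool = False,
        rng: np.random.Generator | None = None,
        metadata: dict | None = None,
        shift_y: float = 0.0,
        exposure_scale: float | None = None,
    ) -> Frame:
        intensity = self.intensity(transmission, shift_x, defocus_z, shift_y=shift_y)
        counts, meta = _expose(intensity, self.camera, noise, rng, scale=exposure_scale)
        meta.update(metadata or {})
        meta.setdefault("lateral_offset", shift_x)
        meta.setdefault("defocus_z", defocus_z)
        return Frame(counts, self.grid, meta)


def form_frame(
    scene: Scene,
    transmission: Transmission,
    defocus_z: float = 0.0,
    camera: CameraModel | None = None,
    noise: bool = False,
    seed: int = 0,
) -> Frame:
    """Simulate a single camera frame of a scene through an SLM transmission."""
    if transmission.grid.n != scene.grid.n:
        raise ValueError("transmission grid does not match scene grid")
    model = ForwardModel(scene, camera)
    rng = np.random.default_rng(seed) if noise else None
    frame = model.frame(transmission, defocus_z=defocus_z, noise=noise, rng=rng)
    frame.metadata["seed"] = seed
    return frame


def acquire_stack(
    scene: Scene,
    transmission: Transmission,
    n_frames: int,
    lateral_step: float = 2.0,
    defocus_z: float = 0.0,
    camera: CameraModel | None = None,
    seed: int = 0,
    noise: bool = False,
) -> FrameStack:
    """Stage-translation acquisition: frame k displaces all scatterers by
    ``k · lateral_step`` μm along x while the background stays static.

    Particles pushed past the field edge wrap around and the frame is
    flagged.  Fresh noise per frame is drawn from a seed stream.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    model = ForwardModel(scene, camera)
    seeds = np.random.SeedSequence(seed).spawn(n_frames)
    frames, meta = [], []
    ext = scene.grid.extent
    # exposure time is set once, at the start of the acquisition
    scale = model.exposure_scale(transmission)
    for k in range(n_frames):
        shift = k * lateral_step
        rng = np.random.default_rng(seeds[k]) if noise else None
        f = model.frame(
            transmission,
            shift_x=shift,
            noise=noise,
            rng=rng,
            metadata={"frame_index": k, "pattern": "static", "seed": seed},
            exposure_scale=scale,
        )
        if any((s.x + shift) >= ext for s in scene.scatterers):
            f.metadata["wrapped"] = True
        frames.append(f.pixels)
        meta.append(f.metadata)
    return FrameStack(np.stack(frames), scene.grid, meta)


def _peak_particle_contrast(model: ForwardModel, transmission: Transmission, defocus_z: float) -> float:
    """Noiseless mean |I/I_bg - 1| at the scatterer positions (±2 px).

    Measures whether particles remain discernible where a detector would
    look for them; light a defocused particle throws far from its own
    position is background, not particle contrast.
    """
    with_p = model.intensity(transmission, defocus_z=defocus_z, include_particles=True)
    without = model.intensity(transmission, defocus_z=defocus_z, include_particles=False)
    grid = model.grid
    vals = []
    half = 2
    for s in model.scene.scatterers:
        i = int(round(s.y / grid.pixel_size))
        j = int(round(s.x / grid.pixel_size))
        sl = (slice(max(i - half, 0), i + half + 1), slice(max(j - half, 0), j + half + 1))
        ratio = with_p[sl] / np.maximum(without[sl], 1e-30)
        vals.append(float(np.abs(ratio - 1.0).max()))
    return float(np.mean(vals)) if vals else 0.0


def alternating_stack(
    scene: Scene,
    focus_transmission: Transmission,
    defocus_fresnel: SLMPattern,
    n_pairs: int,
    camera: CameraModel | None = None,
    seed: int = 0,
    noise: bool = False,
    residual_limit: float = 0.10,
) -> FrameStack:
    """Alternating focused/defocused acquisition for live background division.

    Even frames use ``focus_transmission`` alone; odd frames additionally
    display the Fresnel lens pattern.  Before acquiring, the residual
    particle contrast in the defocused frames is measured (noiselessly) and
    must be below ``residual_limit`` of the focused contrast, otherwise an
    :class:`InsufficientDefocusError` names the measured residual.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    model = ForwardModel(scene, camera)
    fresnel_t = to_transmission(defocus_fresnel)
    defocused_t = Transmission(focus_transmission.values * fresnel_t.values, scene.grid)
    c_foc = _peak_particle_contrast(model, focus_transmission, 0.0)
    c_def = _peak_particle_contrast(model, defocused_t, 0.0)
    if c_foc > 0 and c_def / c_foc >= residual_limit:
        raise InsufficientDefocusError(c_def / c_foc, residual_limit)
    seeds = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    frames, meta = [], []
    # one exposure setting for the whole alternating sequence (the lens
    # pattern toggles at the frame rate; the camera cannot re-meter)
    scale = model.exposure_scale(focus_transmission)
    for k in range(2 * n_pairs):
        focused = k % 2 == 0
        t = focus_transmission if focused else defocused_t
        rng = np.random.default_rng(seeds[k]) if noise else None
        f = model.frame(
            t,
            noise=noise,
            rng=rng,
            exposure_scale=scale,
            metadata={
                "frame_index": k,
                "pattern": "focused" if focused else "defocused",
                "fresnel_pf": None if focused else defocus_fresnel.params.get("power_pf"),
                "seed": seed,
            },
        )
        frames.append(f.pixels)
        meta.append(f.metadata)
    return FrameStack(np.stack(frames), scene.grid, meta)
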