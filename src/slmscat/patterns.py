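"""8-bit SLM patterns and their complex pupil transmissions.

The spatial light modulator sits at a conjugate back-focal plane, so every
pattern is a function of sample-plane spatial frequency.  Patterns are stored
as 8-bit level maps exactly as a device would display them; an effective
device model (polarisation optics folded into a scalar transmission) converts
a pattern to the complex factor multiplied into the pupil field:

* amplitude mode: ``t = level / 255`` (real, in [0, 1]),
* phase mode: ``t = exp(i · 2π · level / 256)`` (unit magnitude).

Filters are generated directly on the simulation pupil grid; the physical
device raster is metadata only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .optics import ComplexField, GridSpec, Plane

__all__ = [
    "PatternMode",
    "SLMPattern",
    "FresnelParams",
    "Transmission",
    "PF_STEP",
    "band_mask",
    "highpass",
    "lowpass",
    "directional_band",
    "fresnel_pattern",
    "defocus_null_power",
    "fork_pattern",
    "grating_pattern",
    "uniform_pattern",
    "to_transmission",
    "identity_transmission",
]

#: Smallest representable change of the Fresnel lens power on an 8-bit device.
PF_STEP = 1.0 / 256.0


class PatternMode(str, enum.Enum):
    AMPLITUDE = "amplitude"
    PHASE = "phase"


@dataclass
class SLMPattern:
    """An 8-bit device pattern on the simulation pupil grid."""

    levels: np.ndarray
    mode: PatternMode
    kind: str
    grid: GridSpec
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.shape != (self.grid.n, self.grid.n):
            raise ValueError("pattern shape does not match grid")
        if self.levels.min() < 0 or self.levels.max() > 255:
            raise ValueError("8-bit device: levels must lie in [0, 255]")
        self.levels = self.levels.astype(np.uint8)
        self.mode = PatternMode(self.mode)


@dataclass(frozen=True)
class FresnelParams:
    """Fresnel zone-plate lens parameters.

    radius_rf
        Pattern radius in pupil-grid pixels; the quadratic phase applies for
        radii <= radius_rf and the level is 0 outside.
    power_pf
        Dimensionless lens power.  The device encodes it in steps of 1/256.
    kappa
        Device constant: equivalent focal shift per unit power, in μm.  The
        encoded phase is φ(ν) = −π·λ·κ·pf·|ν|², so a pattern of power pf
        shifts the object plane by z ≈ κ·pf.
    """

    radius_rf: int
    power_pf: float
    kappa: float = 50.0

    @property
    def quantized_pf(self) -> float:
        """Lens power rounded to the nearest multiple of 1/256."""
        return round(self.power_pf / PF_STEP) * PF_STEP


@dataclass
class Transmission:
    """Complex pupil transmission of a passive device (|t| <= 1)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError("transmission shape does not match grid")
        if np.abs(self.values).max() > 1.0 + 1e-12:
            raise ValueError("passive device: |t| must not exceed 1")

    def apply(self, pupil: ComplexField) -> ComplexField:
        if pupil.plane is not Plane.PUPIL:
            raise ValueError("transmissions apply to pupil-plane fields")
        return ComplexField(self.values * pupil.values, Plane.PUPIL, pupil.grid)


# ---------------------------------------------------------------------------
# Amplitude masks
# ---------------------------------------------------------------------------


def band_mask(grid: GridSpec, nu_lo: float, nu_hi: float) -> SLMPattern:
    """Annular band-pass amplitude mask.

    Passes (level 255) frequencies with ``nu_lo <= |ν| < nu_hi`` and blocks
    (level 0) everything else.  High- and low-pass filters are the two
    half-open special cases.
    """
    if not 0.0 <= nu_lo < nu_hi:
        raise ValueError(f"require 0 <= nu_lo < nu_hi, got [{nu_lo}, {nu_hi})")
    r = grid.freq_radius()
    levels = np.where((r >= nu_lo) & (r < nu_hi), 255, 0)
    return SLMPattern(
        levels,
        PatternMode.AMPLITUDE,
        "bandpass",
        grid,
        {"nu_lo": nu_lo, "nu_hi": nu_hi},
    )


def highpass(grid: GridSpec, nu_c: float) -> SLMPattern:
    """Central occlusion ("black circle") blocking |ν| < nu_c."""
    p = band_mask(grid, nu_c, np.inf)
    p.kind = "highpass"
    p.params = {"nu_c": nu_c}
    return p


def lowpass(grid: GridSpec, nu_c: float) -> SLMPattern:
    """Complement of :func:`highpass`: passes |ν| < nu_c."""
    r = grid.freq_radius()
    levels = np.where(r < nu_c, 255, 0)
    return SLMPattern(levels, PatternMode.AMPLITUDE, "lowpass", grid, {"nu_c": nu_c})


def directional_band(grid: GridSpec, theta_deg: float, thickness: float) -> SLMPattern:
    """Straight band through DC at angle ``theta_deg``.

    Passes frequencies whose perpendicular distance to the line through DC at
    the given angle is <= thickness/2 (cycles/μm).  The band contains DC, so
    the smooth reference field always survives.  Bands at θ and θ+180° are
    identical by construction.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    nx, ny = grid.freq_grids()
    theta = np.deg2rad(theta_deg)
    # distance from the line through origin with direction (cosθ, sinθ)
    dist = np.abs(-np.sin(theta) * nx + np.cos(theta) * ny)
    # graded (anti-aliased) edge one frequency pixel wide: on a coarse pupil
    # raster a binary strip's area beats against the grid as it rotates,
    # imprinting a spurious angular modulation on every particle's contrast
    frac = np.clip((thickness / 2.0 - dist) / grid.freq_step + 0.5, 0.0, 1.0)
    levels = np.round(255.0 * frac).astype(int)
    c = grid.n // 2
    levels[c, c] = 255  # DC always passed
    return SLMPattern(
        levels,
        PatternMode.AMPLITUDE,
        "directional",
        grid,
        {"theta_deg": theta_deg, "thickness": thickness},
    )


def uniform_pattern(grid: GridSpec, level: int = 255, mode: str = "amplitude") -> SLMPattern:
    """Flat pattern; level 255 in amplitude mode is the identity filter."""
    levels = np.full((grid.n, grid.n), level)
    return SLMPattern(levels, PatternMode(mode), "uniform", grid, {"level": level})


# ---------------------------------------------------------------------------
# Phase patterns
# ---------------------------------------------------------------------------


def _phase_to_levels(phase: np.ndarray) -> np.ndarray:
    """Wrap a phase map to [0, 2π) and quantise to 8-bit device levels."""
    wrapped = np.mod(phase, 2.0 * np.pi)
    return np.round(wrapped * 256.0 / (2.0 * np.pi)).astype(int) % 256


def fresnel_pattern(params: FresnelParams, grid: GridSpec) -> SLMPattern:
    """Quadratic-phase zone plate: a diffractive lens on the SLM.

    Phase φ(ν) = −π·λ·κ·pf·|ν|² inside radius ``radius_rf`` (pupil pixels),
    zero outside; pf is quantised to multiples of 1/256 before encoding.

    Raises if the phase would alias across one pupil pixel at the pattern
    edge (zone undersampling).
    """
    if params.radius_rf < 0 or params.radius_rf > grid.n // 2:
        raise ValueError("radius_rf must lie in [0, n/2] pupil pixels")
    pf = params.quantized_pf
    nu_edge = params.radius_rf * grid.freq_step
    # phase gradient per pupil pixel at the pattern edge must stay below pi
    dphi_edge = 2.0 * np.pi * grid.wavelength * params.kappa * abs(pf) * nu_edge * grid.freq_step
    if dphi_edge >= np.pi:
        raise ValueError(
            "zone undersampling: |pf| too large for radius_rf "
            f"(edge phase step {dphi_edge:.2f} rad >= pi)"
        )
    r = grid.freq_radius()
    phase = -np.pi * grid.wavelength * params.kappa * pf * r**2
    levels = _phase_to_levels(phase)
    levels[r > nu_edge] = 0
    return SLMPattern(
        levels,
        PatternMode.PHASE,
        "fresnel",
        grid,
        {"radius_rf": params.radius_rf, "power_pf": pf, "kappa": params.kappa},
    )


def defocus_null_power(grid: GridSpec, kappa: float = 50.0) -> float:
    """Fresnel power that nulls the in-focus particle core.

    The paraxial defocus phase completes one full turn across the aperture
    at z = 2/(λ·ν_NA²); a lens of power pf = z/κ (quantised to the device
    step) suppresses a point scatterer's on-axis image while keeping the
    equivalent defocus — and hence background decorrelation — minimal.
    """
    z_null = 2.0 / (grid.wavelength * grid.nu_na**2)
    return round((z_null / kappa) / PF_STEP) * PF_STEP


def grating_pattern(grid: GridSpec, cycles: float, angle_deg: float = 0.0) -> SLMPattern:
    """Blazed phase grating with ``cycles`` periods across the pupil extent.

    By the Fourier shift theorem a grating of q cycles displaces the image by
    exactly q pixels along the grating direction.
    """
    if cycles < 0:
        raise ValueError("grating frequency must be >= 0")
    nx, ny = grid.freq_grids()
    theta = np.deg2rad(angle_deg)
    # normalised pupil coordinate in [0, 1) along the grating direction
    u = (np.cos(theta) * nx + np.sin(theta) * ny) / (grid.n * grid.freq_step)
    phase = 2.0 * np.pi * cycles * u
    return SLMPattern(
        _phase_to_levels(phase),
        PatternMode.PHASE,
        "grating",
        grid,
        {"cycles": cycles, "angle_deg": angle_deg},
    )


def fork_pattern(grid: GridSpec, charge: int, cycles: float = 0.0, angle_deg: float = 0.0) -> SLMPattern:
    """Fork hologram: a grating with an ℓ-charged azimuthal phase dislocation.

    With zero grating frequency this is a pure vortex phase ℓ·φ, which nulls
    the on-axis image of a point source for ℓ != 0.
    """
    if int(charge) != charge:
        raise ValueError("topological charge must be an integer")
    nx, ny = grid.freq_grids()
    theta = np.deg2rad(angle_deg)
    u = (np.cos(theta) * nx + np.sin(theta) * ny) / (grid.n * grid.freq_step)
    azimuth = np.arctan2(ny, nx)
    phase = 2.0 * np.pi * cycles * u + charge * azimuth
    return SLMPattern(
        _phase_to_levels(phase),
        PatternMode.PHASE,
        "fork",
        grid,
        {"charge": int(charge), "cycles": cycles, "angle_deg": angle_deg},
    )


# ---------------------------------------------------------------------------
# Device model
# ---------------------------------------------------------------------------


def to_transmission(pattern: SLMPattern) -> Transmission:
    """Convert a displayed pattern to its complex pupil transmission.

    The physical phase-retard-then-analyse chain (quarter-wave plate + PBS)
    is collapsed into a direct scalar transmission: amplitude patterns give a
    real factor level/255, phase patterns a unit phasor exp(i·2π·level/256).
    """
    lv = pattern.levels.astype(float)
    if pattern.mode is PatternMode.AMPLITUDE:
        values = lv / 255.0
    else:
        values = np.exp(1j * 2.0 * np.pi * lv / 256.0)
    return Transmission(values, pattern.grid)


def identity_transmission(grid: GridSpec) -> Transmission:
    """All-pass transmission (no pattern displayed)."""
    return Transmission(np.ones((grid.n, grid.n), dtype=complex), grid)
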