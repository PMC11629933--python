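"""Seeded synthetic scenes: nanoparticles, nanorods and coverslip backgrounds.

The generator emulates the samples the filtering experiments run on:

* spin-coated gold nanoparticles (5, 10, 20, 40 nm) on a coverslip imaged in
  water — isotropic point scatterers whose amplitude follows the cubic
  volume law ``s(d) = s0 · (d / 40 nm)³``;
* gold nanorods (40 x 25 nm) — anisotropic scatterers with two orthogonal
  in-plane scattering modes;
* the coverslip reflection — a smooth Gaussian reference envelope plus a
  weak correlated complex speckle field standing in for surface roughness.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import ComplexField, GridSpec, Plane

__all__ = [
    "Anisotropy",
    "Scatterer",
    "BackgroundModel",
    "Scene",
    "DEFAULT_BACKGROUND",
    "REFERENCE_S0",
    "make_particle_scene",
    "make_rod_scene",
    "make_background",
    "isolated_rod_scenes",
    "isolated_sphere_scenes",
    "scene_preset",
    "PRESET_NAMES",
    "scene_to_json",
    "scene_from_json",
]

#: Scattered amplitude of a 40 nm gold particle relative to the unit
#: reference field; gives ~10% unfiltered interference contrast.
REFERENCE_S0 = 0.05


@dataclass(frozen=True)
class Anisotropy:
    """Two-mode in-plane anisotropic response of a rod-like scatterer.

    The long axis points along ``axis_angle_alpha``.  In the pupil the
    longitudinal mode is weighted by |cos(ψ−α)| and the transverse mode by
    |sin(ψ−α)| (ψ = pupil azimuth), with an interferometric phase offset
    between the modes.
    """

    axis_angle_alpha: float  # degrees, in [-90, 90)
    s_long: float
    s_trans: float
    mode_phase_offset: float = np.pi  # radians


@dataclass(frozen=True)
class Scatterer:
    """A point-like scatterer at (x, y) μm from the FOV corner."""

    x: float
    y: float
    z: float = 0.0
    amplitude_s: float = REFERENCE_S0
    phase_phi: float = 0.0
    diameter_nm: float | None = None
    anisotropy: Anisotropy | None = None

    def __post_init__(self) -> None:
        if self.amplitude_s <= 0:
            raise ValueError("amplitude_s must be positive")


@dataclass(frozen=True)
class BackgroundModel:
    """Coverslip-reflection background: Gaussian envelope + complex speckle.

    envelope_width is the 1/e² intensity radius of the illumination /
    reflection envelope in μm; speckle_rms is the RMS amplitude of the
    correlated complex speckle relative to the envelope peak.
    """

    envelope_width: float = 8.0
    envelope_amplitude: float = 1.0
    speckle_rms: float = 0.03
    speckle_correlation_length: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.envelope_width <= 0:
            raise ValueError("envelope_width must be positive")
        if self.speckle_rms < 0:
            raise ValueError("speckle_rms must be >= 0")


#: Background preset used throughout the quantitative experiments.
DEFAULT_BACKGROUND = BackgroundModel()


@dataclass
class Scene:
    """Scatterers + background over one grid."""

    scatterers: list[Scatterer]
    background: BackgroundModel
    grid: GridSpec

    def __post_init__(self) -> None:
        ext = self.grid.extent
        for s in self.scatterers:
            if not (0.0 <= s.x < ext and 0.0 <= s.y < ext):
                raise ValueError(f"scatterer at ({s.x}, {s.y}) outside field of view")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _place_positions(
    rng: np.random.Generator,
    n: int,
    min_separation: float,
    center: float,
    halfwidth: float,
    max_tries: int = 10000,
) -> list[tuple[float, float]]:
    """Uniform non-overlapping positions in a centred square region."""
    if n * min_separation**2 > (2 * halfwidth) ** 2:
        raise ValueError("placement infeasible: too many particles for the region")
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"placement failed after {max_tries} tries "
                f"(n={n}, min_separation={min_separation})"
            )
        tries += 1
        x = center + rng.uniform(-halfwidth, halfwidth)
        y = center + rng.uniform(-halfwidth, halfwidth)
        if all(np.hypot(x - px, y - py) >= min_separation for px, py in positions):
            positions.append((x, y))
    return positions


def make_particle_scene(
    diameters_nm: list[float],
    n_particles: int,
    min_separation: float,
    seed: int,
    grid: GridSpec,
    s0: float = REFERENCE_S0,
    background: BackgroundModel | None = None,
    region_halfwidth: float = 6.0,
    phase_phi: float = 0.0,
) -> Scene:
    """Random scene of isotropic gold nanoparticles.

    Diameters are cycled over the particle list; amplitudes follow the cubic
    volume law ``s0 · (d/40)³``.  Particles are placed uniformly (pairwise
    separation >= ``min_separation``) in the illuminated core of the
    envelope, a centred square of half-size ``region_halfwidth`` μm.
    """
    if background is None:
        background = BackgroundModel(seed=seed)
    rng = np.random.default_rng(seed)
    positions = _place_positions(rng, n_particles, min_separation, grid.center, region_halfwidth)
    scatterers = []
    for k, (x, y) in enumerate(positions):
        d = float(diameters_nm[k % len(diameters_nm)])
        scatterers.append(
            Scatterer(
                x=x,
                y=y,
                amplitude_s=s0 * (d / 40.0) ** 3,
                phase_phi=phase_phi,
                diameter_nm=d,
            )
        )
    return Scene(scatterers, background, grid)


def make_rod_scene(
    axis_angles_deg: list[float],
    seed: int,
    grid: GridSpec,
    s_long: float = REFERENCE_S0,
    s_trans: float = REFERENCE_S0,
    mode_phase_offset: float = np.pi,
    min_separation: float = 3.0,
    background: BackgroundModel | None = None,
    region_halfwidth: float = 6.0,
) -> Scene:
    """Random scene of gold nanorods with given in-plane axis angles.

    With ``s_long == s_trans`` and zero mode phase offset the rod responds
    isotropically; the default π offset is the minimal two-mode model that
    yields a 90°-periodic contrast-magnitude modulation under a rotating
    directional filter.
    """
    for a in axis_angles_deg:
        if not (-90.0 <= a < 90.0):
            raise ValueError("axis angles must lie in [-90, 90)")
    if background is None:
        background = BackgroundModel(seed=seed)
    rng = np.random.default_rng(seed)
    positions = _place_positions(
        rng, len(axis_angles_deg), min_separation, grid.center, region_halfwidth
    )
    scatterers = [
        Scatterer(
            x=x,
            y=y,
            amplitude_s=max(s_long, s_trans),
            anisotropy=Anisotropy(
                axis_angle_alpha=float(alpha),
                s_long=s_long,
                s_trans=s_trans,
                mode_phase_offset=mode_phase_offset,
            ),
        )
        for (x, y), alpha in zip(positions, axis_angles_deg)
    ]
    return Scene(scatterers, background, grid)


def make_background(model: BackgroundModel, grid: GridSpec) -> ComplexField:
    """Realise the background field ``envelope · (1 + speckle)``.

    The speckle is white complex Gaussian noise smoothed with a Gaussian
    kernel of σ = correlation_length/2 (so the field autocorrelation falls
    to 1/e at the requested correlation length) and rescaled to the
    requested RMS.  Deterministic under the model seed.
    """
    x = grid.positions() - grid.center
    xx, yy = np.meshgrid(x, x)
    envelope = model.envelope_amplitude * np.exp(-(xx**2 + yy**2) / model.envelope_width**2)
    values = envelope.astype(complex)
    if model.speckle_rms > 0:
        rng = np.random.default_rng(model.seed)
        white = rng.normal(size=(grid.n, grid.n)) + 1j * rng.normal(size=(grid.n, grid.n))
        sigma_px = (model.speckle_correlation_length / 2.0) / grid.pixel_size
        speckle = gaussian_filter(white.real, sigma_px) + 1j * gaussian_filter(white.imag, sigma_px)
        speckle *= model.speckle_rms / np.sqrt(np.mean(np.abs(speckle) ** 2))
        values = envelope * (1.0 + speckle)
    return ComplexField(values, Plane.SAMPLE, grid)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("aunp5", "aunp10", "aunp20", "aunp40", "aunr", "sphere-control")


def scene_preset(name: str, seed: int, grid: GridSpec, n_particles: int = 12) -> Scene:
    """Named fixture scenes used by the quantitative experiments.

    ``aunp5`` … ``aunp40``: nanoparticle scenes of one size on the default
    background; ``aunr``: 10 rods with random axis angles; ``sphere-control``:
    isotropic particles for the directional-filter control.
    """
    if name.startswith("aunp"):
        d = float(name[4:])
        if d not in (5.0, 10.0, 20.0, 40.0):
            raise ValueError(f"unknown preset {name!r}")
        return make_particle_scene([d], n_particles, 3.0, seed, grid)
    if name == "aunr":
        rng = np.random.default_rng(seed + 7)
        angles = rng.uniform(-90.0, 90.0, size=10).tolist()
        return make_rod_scene(angles, seed, grid)
    if name == "sphere-control":
        return make_particle_scene([40.0], 10, 3.0, seed, grid)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def isolated_rod_scenes(
    n_rods: int,
    seed: int,
    grid: GridSpec,
    s_long: float = REFERENCE_S0,
    s_trans: float = REFERENCE_S0,
    mode_phase_offset: float = np.pi,
) -> list[Scene]:
    """One-rod-per-field scenes with random axis angles.

    Directional filtering stretches every particle into a streak comparable
    to the illuminated area, so orientation experiments image each rod in
    its own field of view (as on a sparsely coated coverslip) and pool the
    per-particle curves afterwards.
    """
    rng = np.random.default_rng(seed + 7)
    angles = rng.uniform(-90.0, 90.0, size=n_rods)
    return [
        make_rod_scene(
            [float(a)],
            seed + 1000 * k,
            grid,
            s_long=s_long,
            s_trans=s_trans,
            mode_phase_offset=mode_phase_offset,
        )
        for k, a in enumerate(angles)
    ]


def isolated_sphere_scenes(n_spheres: int, seed: int, grid: GridSpec) -> list[Scene]:
    """One-sphere-per-field control scenes for the directional-filter sweep."""
    return [
        make_particle_scene([40.0], 1, 3.0, seed + 1000 * k, grid)
        for k in range(n_spheres)
    ]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def scene_to_json(scene: Scene) -> str:
    payload = {
        "grid": asdict(scene.grid),
        "background": asdict(scene.background),
        "scatterers": [asdict(s) for s in scene.scatterers],
    }
    return json.dumps(payload, indent=2)


def scene_from_json(text: str) -> Scene:
    payload = json.loads(text)
    grid = GridSpec(**payload["grid"])
    background = BackgroundModel(**payload["background"])
    scatterers = []
    for rec in payload["scatterers"]:
        aniso = rec.pop("anisotropy", None)
        scatterers.append(
            Scatterer(**rec, anisotropy=Anisotropy(**aniso) if aniso else None)
        )
    return Scene(scatterers, background, grid)
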