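"""Quantitative measurement pipeline.

Implements the contrast-measurement chain used by all experiments —
median-projection normalisation, particle detection, sinc-profile fitting,
``C = (Is − Ib)/Ib`` — plus the parameter sweeps built on it: the high-pass
cutoff sweep with its optimal-cutoff/enhancement summary, the Fresnel-power
to axial-position calibration, defocus-division background correction, and
the directional-filter orientation analysis (per-particle contrast curves,
align-and-merge, free-period sine fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter, map_coordinates, median_filter
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .imaging import CameraModel, ForwardModel, Frame, FrameStack
from .optics import PSF_SIGMA_UM, GridSpec
from .patterns import (
    Transmission,
    directional_band,
    highpass,
    identity_transmission,
    to_transmission,
)
from .scenes import Scene

__all__ = [
    "AcquisitionConfig",
    "ContrastRecord",
    "SincFit",
    "SweepResult",
    "CalibrationCurve",
    "OrientationCurves",
    "SineFit",
    "OrientationEstimate",
    "median_normalize",
    "displaced_median_background",
    "detect_particles",
    "fit_profile_sinc",
    "contrast",
    "bootstrap_ci",
    "highpass_sweep",
    "optimal_cutoff",
    "fresnel_calibration",
    "restore_focus",
    "divide_background",
    "orientation_sweep",
    "orientation_survey",
    "align_merge",
    "fit_sine",
    "estimate_orientation",
]


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """How the pipeline acquires and measures a scene.

    The lateral-displacement protocol moves particles by ``lateral_step`` μm
    per frame over a static background so the per-pixel median projection is
    particle-free.
    """

    n_frames: int = 16
    lateral_step: float = 2.0
    noise: bool = False
    seed: int = 0
    camera: CameraModel = field(default_factory=CameraModel)
    percentile: float = 64.0
    min_separation_px: int = 5
    snr_min: float = 5.0
    match_radius_px: float = 8.0
    profile_angle_deg: float = 0.0
    psf_sigma_um: float = PSF_SIGMA_UM
    n_boot: int = 1000


@dataclass
class ContrastRecord:
    """Per-particle contrast under one filter setting."""

    particle_id: int
    Is: float
    Ib: float
    C: float
    x: float
    y: float
    filter_params: dict = field(default_factory=dict)


@dataclass
class SincFit:
    """Least-squares sinc fit of a line profile across a particle."""

    x0: float
    width_w: float
    amplitude_A: float
    baseline_Ib: float
    rss: float

    @property
    def Is(self) -> float:
        return self.baseline_Ib + self.amplitude_A


@dataclass
class SweepResult:
    """Contrast statistics over one swept filter parameter."""

    parameter: str
    values: np.ndarray
    mean_contrast: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    per_particle: pd.DataFrame

    def __post_init__(self) -> None:
        ok = ~np.isnan(self.mean_contrast)
        if np.any(self.ci95_low[ok] > self.mean_contrast[ok]) or np.any(
            self.mean_contrast[ok] > self.ci95_high[ok]
        ):
            raise ValueError("CI bounds must bracket the mean")


@dataclass
class CalibrationCurve:
    """Fresnel lens power pf mapped to equivalent stage defocus z."""

    pf_values: np.ndarray
    z_equivalents: np.ndarray
    slope: float  # μm per unit pf
    quantization_step_z: float  # μm, slope / 256
    pf_contrast: np.ndarray
    z_grid: np.ndarray
    z_contrast: np.ndarray


@dataclass
class OrientationCurves:
    """Per-particle signed contrast versus directional-filter angle."""

    thetas: np.ndarray  # degrees
    curves: dict[int, np.ndarray]  # particle id -> C(theta), nan = lost
    axis_angles: dict[int, float | None] = field(default_factory=dict)


@dataclass
class SineFit:
    period: float  # degrees
    phase: float  # degrees
    amplitude: float
    offset: float


@dataclass
class OrientationEstimate:
    """Measured in-plane axis angle, modulo the 90° model ambiguity."""

    alpha_deg: float | None
    modulation_depth: float

    @property
    def oriented(self) -> bool:
        return self.alpha_deg is not None


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def median_normalize(stack: FrameStack) -> FrameStack:
    """Divide every frame by the per-pixel median projection of the stack."""
    if len(stack) < 3:
        raise ValueError("median normalisation needs at least 3 frames")
    med = np.median(stack.pixels, axis=0)
    zeros = np.argwhere(med == 0.0)
    if zeros.size:
        i, j = zeros[0]
        raise ValueError(f"median projection is zero at pixel ({i}, {j})")
    return FrameStack(stack.pixels / med, stack.grid, [dict(m) for m in stack.metadata])


def displaced_median_background(stack: FrameStack) -> Frame:
    """Median frame of a lateral-displacement stack, used as the division
    background for raw frames."""
    steps = {m.get("lateral_offset", 0.0) for m in stack.metadata}
    if len(stack) == 1:
        warnings.warn("single-frame stack: median is the frame itself")
    elif len(steps) <= 1:
        warnings.warn("stack has no lateral displacement; particles will survive the median")
    med = np.median(stack.pixels, axis=0)
    return Frame(med, stack.grid, {"kind": "median_background", "n_frames": len(stack)})


def divide_background(focused: Frame, defocused: Frame) -> Frame:
    """Live correction: pixelwise division of the focused frame by the
    defocused frame."""
    if focused.pixels.shape != defocused.pixels.shape:
        raise ValueError("frames must share a shape")
    if np.any(defocused.pixels <= 0.0):
        raise ValueError("defocused frame has non-positive pixels; cannot divide")
    return Frame(
        focused.pixels / defocused.pixels,
        focused.grid,
        {"kind": "defocus_divided"},
    )


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_particles(
    image: Frame | np.ndarray,
    grid: GridSpec | None = None,
    percentile: float = 64.0,
    min_separation_px: int = 5,
    snr_min: float = 5.0,
    psf_sigma_um: float = PSF_SIGMA_UM,
    support_mask: np.ndarray | None = None,
    counts_map: np.ndarray | None = None,
    read_noise: float = 5.0,
) -> list[tuple[float, float, float]]:
    """Locate particle-like deviations in a normalised frame.

    The deviation image |I − 1| is band-passed with a difference of
    Gaussians matched to the PSF scale, then candidate peaks must (a) exceed
    the given intensity percentile of the band-passed deviation and (b) be
    significant against the robust noise scale (``snr_min`` × MAD/0.6745).
    When ``counts_map`` (the detector counts behind the normalised image) is
    given, deviations are standardised by the local shot-noise scale
    (multiplied by sqrt(counts)), so dim regions of the illumination
    envelope do not flood the detector with noise peaks.
    Peaks closer than ``min_separation_px`` keep only the brighter one, and
    secondary maxima in the diffraction-ring zone of a much stronger peak
    are suppressed.

    ``support_mask`` restricts detection to the illuminated region —
    normalised ratios are meaningless where the reference background holds
    no light (a dark pixel divided by a dark pixel).

    Returns (x, y, strength) tuples with positions in μm from the FOV corner
    (centroid-refined).
    """
    if isinstance(image, Frame):
        grid = image.grid
        pixels = image.pixels
    else:
        if grid is None:
            raise ValueError("grid required for a bare array")
        pixels = np.asarray(image, dtype=float)
    sigma_px = psf_sigma_um / grid.pixel_size
    dev = np.abs(pixels - 1.0)
    if counts_map is not None:
        counts = np.clip(counts_map, 0.0, None)
        dev = dev * counts / np.sqrt(counts + read_noise**2)
    if support_mask is not None:
        # continue the typical deviation level outside the mask: a hard step
        # to zero would ring through the filters and pile false peaks along
        # the illumination boundary
        fill = float(np.median(dev[support_mask])) if support_mask.any() else 0.0
        dev = np.where(support_mask, dev, fill)
    smooth_sigma = sigma_px / 2.0
    # matched smoothing minus a robust (median) local background: a median
    # surround ignores neighbouring particles' spots, which a Gaussian
    # surround would subtract from the peak in a dense field
    surround = int(round(6.0 * sigma_px)) | 1
    band = gaussian_filter(dev, smooth_sigma) - median_filter(dev, size=surround)
    if support_mask is not None:
        # peaks must sit clear of the illumination boundary, where particle
        # diffraction tails over a dim reference mimic strong deviations
        interior = binary_erosion(
            support_mask, iterations=max(1, int(round(smooth_sigma)))
        )
    else:
        interior = None
    sample = band[support_mask] if support_mask is not None else band.ravel()
    raw = dev[support_mask] if support_mask is not None else dev.ravel()
    # pixel noise estimated on the unsmoothed deviations, propagated through
    # the matched filter (white-noise std gain of a 2-D Gaussian filter);
    # the deviations are folded (absolute values), and for a half-normal
    # sample MAD = 0.3986 sigma of the underlying noise
    noise_scale = np.median(np.abs(raw - np.median(raw))) / 0.3986
    noise_scale *= 1.0 / (2.0 * np.sqrt(np.pi) * smooth_sigma)
    threshold = max(
        float(np.percentile(sample, percentile)), snr_min * float(noise_scale)
    )
    if threshold <= 0:
        # noiseless frame: fall back to a fraction of the strongest response
        threshold = 0.05 * float(band.max())
    if threshold <= 0:
        return []
    peaks = peak_local_max(
        band, min_distance=int(min_separation_px), threshold_abs=threshold
    )
    if interior is not None and peaks.size:
        peaks = peaks[interior[peaks[:, 0], peaks[:, 1]]]
    # suppress diffraction-ring sidelobes: drop peaks much weaker than a
    # nearby accepted peak — the first ring (~3 PSF sigmas, sidelobe ratio
    # ~0.22) and the fainter outer rings (out to ~8 sigmas, ratio < 0.1)
    strengths = np.array([band[i, j] for i, j in peaks])
    order = np.argsort(-strengths)
    ring_zones = ((3.0 * sigma_px, 0.35), (8.0 * sigma_px, 0.10), (np.inf, 0.05))
    accepted: list[tuple[int, int, float]] = []
    for k in order:
        i, j = peaks[k]
        st = strengths[k]
        shadowed = any(
            np.hypot(i - ai, j - aj) < radius and st < ratio * ast
            for ai, aj, ast in accepted
            for radius, ratio in ring_zones
        )
        if not shadowed:
            accepted.append((i, j, float(st)))
    detections: list[tuple[float, float, float]] = []
    half = max(2, int(round(sigma_px)))
    n = grid.n
    for i, j, st in accepted:
        i0, i1 = max(i - half, 0), min(i + half + 1, n)
        j0, j1 = max(j - half, 0), min(j + half + 1, n)
        window = band[i0:i1, j0:j1]
        w = np.clip(window, 0.0, None)
        if w.sum() == 0:
            continue
        ii, jj = np.mgrid[i0:i1, j0:j1]
        yc = float((ii * w).sum() / w.sum()) * grid.pixel_size
        xc = float((jj * w).sum() / w.sum()) * grid.pixel_size
        detections.append((xc, yc, st))
    detections.sort(key=lambda d: -d[2])
    return detections


def _match_to_scene(
    detections: list[tuple[float, float, float]],
    scene: Scene,
    radius_px: float,
) -> dict[int, tuple[float, float]]:
    """Greedy nearest match of detections to planted scatterer positions."""
    radius = radius_px * scene.grid.pixel_size
    matched: dict[int, tuple[float, float]] = {}
    for pid, s in enumerate(scene.scatterers):
        best, best_d = None, np.inf
        for (x, y, _) in detections:
            d = np.hypot(x - s.x, y - s.y)
            if d < best_d:
                best, best_d = (x, y), d
        if best is not None and best_d <= radius:
            matched[pid] = best
    return matched


# ---------------------------------------------------------------------------
# Profile fitting and contrast
# ---------------------------------------------------------------------------


def contrast(Is: float, Ib: float) -> float:
    """Interference contrast C = (Is − Ib)/Ib."""
    if Ib <= 0:
        raise ValueError("background intensity Ib must be positive")
    return (Is - Ib) / Ib


def fit_profile_sinc(
    image: Frame | np.ndarray,
    center: tuple[float, float],
    angle_deg: float = 0.0,
    half_length_px: int | None = None,
    grid: GridSpec | None = None,
    psf_sigma_um: float = PSF_SIGMA_UM,
) -> SincFit:
    """Fit ``Ib + A·sinc((x − x0)/w)`` to a line profile across a particle.

    The profile runs through ``center`` (μm) at ``angle_deg``; x is the
    signed distance along the profile in μm.  The normalised sinc's first
    zero sits at ``w``.  A dark (interferometrically inverted) particle
    yields A < 0 — the sign is preserved, never folded.
    """
    if isinstance(image, Frame):
        grid = image.grid
        pixels = image.pixels
    else:
        if grid is None:
            raise ValueError("grid required for a bare array")
        pixels = np.asarray(image, dtype=float)
    if half_length_px is None:
        half_length_px = int(round(10.0 * psf_sigma_um / grid.pixel_size))
    t = np.arange(-half_length_px, half_length_px + 1, dtype=float)
    theta = np.deg2rad(angle_deg)
    cj = center[0] / grid.pixel_size + t * np.cos(theta)
    ci = center[1] / grid.pixel_size + t * np.sin(theta)
    n = grid.n
    if cj.min() < 0 or cj.max() > n - 1 or ci.min() < 0 or ci.max() > n - 1:
        raise ValueError("profile extends outside the image")
    y = map_coordinates(pixels, np.vstack([ci, cj]), order=1)
    x = t * grid.pixel_size

    # the profile is centred on the detected spot: initialise from (and keep
    # the fitted position within) the central two PSF widths so the fit
    # cannot latch onto an unrelated feature further out
    x0_limit = 2.0 * psf_sigma_um
    central = np.abs(x) <= x0_limit
    baseline0 = float(np.median(y))
    k_ext = int(np.argmax(np.where(central, np.abs(y - baseline0), -np.inf)))
    amp0 = float(y[k_ext] - baseline0)
    x00 = float(x[k_ext])

    def model(xx: np.ndarray, ib: float, a: float, x0: float, w: float) -> np.ndarray:
        return ib + a * np.sinc((xx - x0) / w)

    p0 = [baseline0, amp0, x00, psf_sigma_um]
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=p0,
            bounds=(
                [-np.inf, -np.inf, -x0_limit, grid.pixel_size / 4.0],
                [np.inf, np.inf, x0_limit, np.inf],
            ),
            maxfev=5000,
        )
    except RuntimeError as err:
        rss0 = float(np.sum((y - model(x, *p0)) ** 2))
        raise RuntimeError(
            f"sinc fit failed to converge (init {p0}, rss {rss0:.3g})"
        ) from err
    rss = float(np.sum((y - model(x, *popt)) ** 2))
    return SincFit(
        x0=float(popt[2]),
        width_w=float(abs(popt[3])),
        amplitude_A=float(popt[1]),
        baseline_Ib=float(popt[0]),
        rss=rss,
    )


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 95.0
) -> tuple[float, float]:
    """Bootstrap confidence interval of the mean, resampling particles."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - level) / 2.0, 100 - (100 - level) / 2.0])
    mean = float(values.mean())
    return (min(float(lo), mean), max(float(hi), mean))


# ---------------------------------------------------------------------------
# Shared pipeline step
# ---------------------------------------------------------------------------


def _normalized_frame(
    model: ForwardModel,
    transmission: Transmission,
    config: AcquisitionConfig,
    defocus_z: float = 0.0,
    noise_seed: int = 0,
    shift_angle_deg: float = 0.0,
) -> tuple[Frame, np.ndarray] | None:
    """Acquire a displaced stack through one transmission and return the
    median-normalised first frame plus the illumination support mask.

    ``shift_angle_deg`` sets the stage-translation direction; experiments
    with strongly anisotropic PSFs displace perpendicular to the streak so
    the median projection stays particle-free.
    """
    seeds = np.random.SeedSequence((config.seed, noise_seed)).spawn(config.n_frames)
    ux = float(np.cos(np.deg2rad(shift_angle_deg)))
    uy = float(np.sin(np.deg2rad(shift_angle_deg)))
    # exposure metered once per stack, on the first frame
    scale = model.exposure_scale(transmission, defocus_z=defocus_z)
    if scale <= 0.0:
        return None
    frames = []
    for k in range(config.n_frames):
        rng = np.random.default_rng(seeds[k]) if config.noise else None
        f = model.frame(
            transmission,
            shift_x=k * config.lateral_step * ux,
            shift_y=k * config.lateral_step * uy,
            defocus_z=defocus_z,
            noise=config.noise,
            rng=rng,
            exposure_scale=scale,
        )
        if "warning" in f.metadata:  # fully blocked: nothing to measure
            return None
        frames.append(f.pixels)
    med = np.median(np.stack(frames), axis=0)
    if med.max() <= 0:
        return None
    # measurable only where the reference background actually holds light;
    # elsewhere the ratio of two dark pixels carries no contrast information
    support = med > 0.01 * med.max()
    norm0 = np.where(support, frames[0] / np.where(support, med, 1.0), 1.0)
    frame = Frame(
        norm0, model.grid, {"kind": "median_normalized", "median_counts": med}
    )
    return frame, support


def _fit_records(
    frame0: Frame,
    positions: dict[int, tuple[float, float]],
    config: AcquisitionConfig,
    filter_params: dict | None = None,
    profile_angle_deg: float | None = None,
) -> list[ContrastRecord]:
    """Sinc-fit the profile at each particle position and build records."""
    angle = (
        profile_angle_deg if profile_angle_deg is not None else config.profile_angle_deg
    )
    records: list[ContrastRecord] = []
    for pid, (x, y) in positions.items():
        try:
            fit = fit_profile_sinc(
                frame0, (x, y), angle_deg=angle, psf_sigma_um=config.psf_sigma_um
            )
        except (RuntimeError, ValueError):
            continue
        if fit.baseline_Ib <= 0:
            continue
        records.append(
            ContrastRecord(
                particle_id=pid,
                Is=fit.Is,
                Ib=fit.baseline_Ib,
                C=contrast(fit.Is, fit.baseline_Ib),
                x=x,
                y=y,
                filter_params=dict(filter_params or {}),
            )
        )
    return records


def _measure_stack(
    model: ForwardModel,
    transmission: Transmission,
    config: AcquisitionConfig,
    defocus_z: float = 0.0,
    filter_params: dict | None = None,
    noise_seed: int = 0,
) -> list[ContrastRecord]:
    """Acquire a displaced stack through one transmission, normalise, detect,
    fit, and return per-particle contrast records (missing particles absent)."""
    out = _normalized_frame(model, transmission, config, defocus_z, noise_seed)
    if out is None:
        return []
    frame0, support = out
    detections = detect_particles(
        frame0,
        percentile=config.percentile,
        min_separation_px=config.min_separation_px,
        snr_min=config.snr_min,
        psf_sigma_um=config.psf_sigma_um,
        support_mask=support,
        counts_map=frame0.metadata.get("median_counts"),
        read_noise=config.camera.read_noise,
    )
    matched = _match_to_scene(detections, model.scene, config.match_radius_px)
    return _fit_records(frame0, matched, config, filter_params)


# ---------------------------------------------------------------------------
# High-pass sweep
# ---------------------------------------------------------------------------


def highpass_sweep(
    scene: Scene,
    cutoffs: list[float],
    config: AcquisitionConfig | None = None,
) -> SweepResult:
    """Contrast versus high-pass cutoff frequency.

    ``cutoffs`` must include 0 (the unfiltered baseline).  For each cutoff
    the full pipeline runs (acquire, median-normalise, detect, sinc-fit);
    cutoffs where nothing is detected are recorded as missing, never imputed.
    """
    config = config or AcquisitionConfig()
    cutoffs = list(cutoffs)
    if len(cutoffs) < 2 or 0.0 not in cutoffs:
        raise ValueError("need >= 2 cutoffs including the unfiltered baseline 0")
    model = ForwardModel(scene, config.camera)
    rows = []
    means, los, his = [], [], []
    for idx, nu_c in enumerate(cutoffs):
        t = (
            identity_transmission(scene.grid)
            if nu_c == 0.0
            else to_transmission(highpass(scene.grid, nu_c))
        )
        records = _measure_stack(
            model, t, config, filter_params={"nu_c": nu_c}, noise_seed=idx
        )
        cs = np.array([r.C for r in records])
        for r in records:
            rows.append(
                {
                    "particle_id": r.particle_id,
                    "nu_c": nu_c,
                    "C": r.C,
                    "Is": r.Is,
                    "Ib": r.Ib,
                    "x": r.x,
                    "y": r.y,
                }
            )
        if cs.size == 0:
            means.append(np.nan)
            los.append(np.nan)
            his.append(np.nan)
        else:
            lo, hi = bootstrap_ci(cs, n_boot=config.n_boot, seed=config.seed + idx)
            means.append(float(cs.mean()))
            los.append(lo)
            his.append(hi)
    return SweepResult(
        parameter="nu_c",
        values=np.asarray(cutoffs, dtype=float),
        mean_contrast=np.asarray(means),
        ci95_low=np.asarray(los),
        ci95_high=np.asarray(his),
        per_particle=pd.DataFrame(rows),
    )


def optimal_cutoff(sweep: SweepResult) -> tuple[float, float, float]:
    """Summarise a high-pass sweep: (ν*, period 1/ν*, enhancement factor).

    ν* is the mean-contrast argmax over nonzero cutoffs (ties break toward
    the smallest, least destructive cutoff); the enhancement factor is the
    mean contrast at ν* divided by the unfiltered baseline.
    """
    values = sweep.values
    means = sweep.mean_contrast
    base = np.where(values == 0.0)[0]
    if base.size == 0:
        raise ValueError("sweep lacks the unfiltered baseline (cutoff 0)")
    c0 = means[base[0]]
    if not np.isfinite(c0) or c0 <= 0:
        raise ValueError(f"baseline contrast must be positive, got {c0}")
    nz = [(v, m) for v, m in zip(values, means) if v > 0 and np.isfinite(m)]
    if not nz:
        raise ValueError("no nonzero cutoff produced a measurable contrast")
    best_c = max(m for _, m in nz)
    nu_star = min(v for v, m in nz if m == best_c)
    period_star = 1.0 / nu_star
    return nu_star, period_star, float(best_c / c0)


# ---------------------------------------------------------------------------
# Fresnel calibration and focus restoration
# ---------------------------------------------------------------------------


def _mean_contrast(
    model: ForwardModel,
    transmission: Transmission,
    config: AcquisitionConfig,
    defocus_z: float = 0.0,
    noise_seed: int = 0,
) -> float:
    records = _measure_stack(model, transmission, config, defocus_z, noise_seed=noise_seed)
    if not records:
        return np.nan
    return float(np.mean([r.C for r in records]))


def fresnel_calibration(
    scene: Scene,
    pf_values: list[float],
    z_values: list[float],
    config: AcquisitionConfig | None = None,
    radius_rf: int | None = None,
    kappa: float = 50.0,
) -> CalibrationCurve:
    """Map Fresnel lens power pf to equivalent stage defocus z.

    Runs the contrast pipeline as a function of pf (stage fixed) and as a
    function of stage z (no pattern), then matches each pf to the z with
    equal mean contrast by interpolating the z-curve on its monotone
    out-of-focus branch.  The slope of the fitted line through the origin is
    the lens calibration in μm per unit pf; one 8-bit device step changes
    focus by slope/256.
    """
    from .patterns import FresnelParams, fresnel_pattern

    config = config or AcquisitionConfig()
    grid = scene.grid
    if radius_rf is None:
        radius_rf = int(np.ceil(grid.nu_na / grid.freq_step)) + 2
    model = ForwardModel(scene, config.camera)
    ident = identity_transmission(grid)

    z_grid = np.asarray(sorted(z_values), dtype=float)
    z_contrast = np.array(
        [_mean_contrast(model, ident, config, defocus_z=z, noise_seed=100 + i)
         for i, z in enumerate(z_grid)]
    )
    pf_arr = np.asarray(pf_values, dtype=float)
    pf_contrast = np.array(
        [
            _mean_contrast(
                model,
                to_transmission(
                    fresnel_pattern(FresnelParams(radius_rf, pf, kappa), grid)
                )
                if pf != 0.0
                else ident,
                config,
                noise_seed=200 + i,
            )
            for i, pf in enumerate(pf_arr)
        ]
    )

    ok = np.isfinite(z_contrast)
    zg, zc = z_grid[ok], z_contrast[ok]
    if zg.size < 2:
        raise ValueError("z sweep produced too few measurable points")
    # monotone decreasing branch away from focus (z >= 0)
    order = np.argsort(zc)
    zc_mono, zg_mono = zc[order], zg[order]
    lo, hi = float(zc.min()), float(zc.max())
    z_eq = []
    for c in pf_contrast:
        if not np.isfinite(c) or not (lo <= c <= hi):
            z_eq.append(np.nan)
        else:
            z_eq.append(float(np.interp(c, zc_mono, zg_mono)))
    z_eq = np.asarray(z_eq)
    if np.all(np.isnan(z_eq[pf_arr != 0.0])):
        raise ValueError("contrast ranges of the pf and z sweeps do not overlap")
    sel = np.isfinite(z_eq)
    if np.any(pf_arr[sel] != 0.0):
        p = pf_arr[sel]
        slope = float(np.sum(p * z_eq[sel]) / np.sum(p * p))
    else:
        slope = np.nan
    return CalibrationCurve(
        pf_values=pf_arr,
        z_equivalents=z_eq,
        slope=slope,
        quantization_step_z=slope / 256.0,
        pf_contrast=pf_contrast,
        z_grid=z_grid,
        z_contrast=z_contrast,
    )


def restore_focus(
    scene: Scene,
    stage_z: float,
    pf_values: list[float],
    config: AcquisitionConfig | None = None,
    radius_rf: int | None = None,
    kappa: float = 50.0,
) -> tuple[float, float]:
    """Recover focus lost to a stage translation with a Fresnel lens.

    Returns (best pf, recovered fraction of the in-focus mean contrast).
    """
    from .patterns import FresnelParams, fresnel_pattern

    config = config or AcquisitionConfig()
    grid = scene.grid
    if radius_rf is None:
        radius_rf = int(np.ceil(grid.nu_na / grid.freq_step)) + 2
    model = ForwardModel(scene, config.camera)
    ident = identity_transmission(grid)
    c_focus = _mean_contrast(model, ident, config, defocus_z=0.0)
    best_pf, best_c = 0.0, -np.inf
    for i, pf in enumerate(pf_values):
        t = (
            ident
            if pf == 0.0
            else to_transmission(fresnel_pattern(FresnelParams(radius_rf, pf, kappa), grid))
        )
        c = _mean_contrast(model, t, config, defocus_z=stage_z, noise_seed=300 + i)
        if np.isfinite(c) and c > best_c:
            best_pf, best_c = pf, c
    return best_pf, float(best_c / c_focus)


# ---------------------------------------------------------------------------
# Orientation analysis
# ---------------------------------------------------------------------------


def orientation_sweep(
    scene: Scene,
    thetas: np.ndarray | None = None,
    band_thickness: float = 0.2,
    config: AcquisitionConfig | None = None,
) -> OrientationCurves:
    """Per-particle contrast versus directional-filter angle.

    The default grid is −90° … +90° in 5° steps (37 angles).  A particle
    that vanishes at some angle (the filter crossing its dark orientation)
    is recorded as missing at that angle.
    """
    config = config or AcquisitionConfig()
    if thetas is None:
        thetas = np.arange(-90.0, 90.0 + 1e-9, 5.0)
    thetas = np.asarray(thetas, dtype=float)
    if np.any(np.diff(thetas) <= 0) or thetas.min() < -90 or thetas.max() > 90:
        raise ValueError("thetas must be sorted and within [-90, 90]")
    model = ForwardModel(scene, config.camera)
    curves = {
        pid: np.full(thetas.size, np.nan) for pid in range(len(scene.scatterers))
    }
    # particles are located once, without the directional filter; the band
    # turns each spot into a streak whose position does not move with angle,
    # so contrast at every angle is measured at the reference positions.
    # A scatterer invisible in the unfiltered image (the two-mode rod model
    # cancels exactly there) keeps its planted position for bookkeeping.
    reference = _measure_stack(model, identity_transmission(scene.grid), config)
    positions = {r.particle_id: (r.x, r.y) for r in reference}
    for pid, sc in enumerate(scene.scatterers):
        positions.setdefault(pid, (sc.x, sc.y))
    for i, th in enumerate(thetas):
        t = to_transmission(directional_band(scene.grid, th, band_thickness))
        # the streak extends perpendicular to the filter angle; displacing
        # along theta crosses the streak, keeping the median particle-free
        out = _normalized_frame(
            model, t, config, noise_seed=400 + i, shift_angle_deg=th
        )
        if out is None:
            continue
        frame0, _ = out
        # the streak is sharp along the filter angle: profile along theta
        records = _fit_records(
            frame0,
            positions,
            config,
            filter_params={"theta": th},
            profile_angle_deg=th,
        )
        for r in records:
            curves[r.particle_id][i] = r.C
    axis_angles = {
        pid: (s.anisotropy.axis_angle_alpha if s.anisotropy else None)
        for pid, s in enumerate(scene.scatterers)
    }
    return OrientationCurves(thetas=thetas, curves=curves, axis_angles=axis_angles)


def orientation_survey(
    scenes: list[Scene],
    thetas: np.ndarray | None = None,
    band_thickness: float = 0.2,
    config: AcquisitionConfig | None = None,
) -> OrientationCurves:
    """Directional-filter sweep pooled over several fields of view.

    Runs :func:`orientation_sweep` on each scene (typically one particle per
    field) and merges the curves under unique particle ids.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    merged_curves: dict[int, np.ndarray] = {}
    merged_axes: dict[int, float | None] = {}
    thetas_out: np.ndarray | None = None
    offset = 0
    for scene in scenes:
        res = orientation_sweep(
            scene, thetas=thetas, band_thickness=band_thickness, config=config
        )
        thetas_out = res.thetas
        for pid, c in res.curves.items():
            merged_curves[offset + pid] = c
            merged_axes[offset + pid] = res.axis_angles[pid]
        offset += len(scene.scatterers)
    return OrientationCurves(
        thetas=thetas_out, curves=merged_curves, axis_angles=merged_axes
    )


def align_merge(curves: OrientationCurves) -> tuple[np.ndarray, np.ndarray]:
    """Pool relative contrast-magnitude curves with maxima aligned at 0°.

    Each particle's |C(θ)| is normalised to its own maximum, circularly
    shifted so the maximum sits at 0°, and all points are merged.  Returns
    (θ offsets in degrees, relative contrast values).
    """
    thetas = curves.thetas
    if not curves.curves:
        raise ValueError("no curves to merge")
    step = float(np.median(np.diff(thetas)))
    span = thetas[-1] - thetas[0] + step
    all_t, all_v = [], []
    for c in curves.curves.values():
        mag = np.abs(c)
        if np.all(np.isnan(mag)) or np.nanmax(mag) == 0:
            continue
        k = int(np.nanargmax(mag))
        rel = mag / np.nanmax(mag)
        shifted = thetas - thetas[k]
        # wrap offsets into a single period of the angular window
        shifted = (shifted + span / 2.0) % span - span / 2.0
        ok = ~np.isnan(rel)
        all_t.append(shifted[ok])
        all_v.append(rel[ok])
    if not all_t:
        raise ValueError("all curves empty")
    t = np.concatenate(all_t)
    v = np.concatenate(all_v)
    order = np.argsort(t)
    return t[order], v[order]


def fit_sine(
    thetas: np.ndarray,
    values: np.ndarray,
    period_init: float = 90.0,
) -> SineFit:
    """Fit ``c + a·sin(2π(θ − θ₀)/T)`` with the period T free."""
    thetas = np.asarray(thetas, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    thetas, values = thetas[ok], values[ok]

    def model(th: np.ndarray, c: float, a: float, th0: float, period: float) -> np.ndarray:
        return c + a * np.sin(2.0 * np.pi * (th - th0) / period)

    amp0 = (values.max() - values.min()) / 2.0
    inits = [
        [float(values.mean()), amp0, -period_init / 4.0, period_init],
        [float(values.mean()), amp0, 0.0, period_init],
        [float(values.mean()), amp0, period_init / 4.0, period_init],
    ]
    last_err: Exception | None = None
    for p0 in inits:
        try:
            popt, _ = curve_fit(model, thetas, values, p0=p0, maxfev=10000)
            return SineFit(
                period=float(abs(popt[3])),
                phase=float(popt[2]),
                amplitude=float(abs(popt[1])),
                offset=float(popt[0]),
            )
        except RuntimeError as err:
            last_err = err
    raise RuntimeError(f"sine fit failed for all initialisations {inits}") from last_err


def estimate_orientation(
    thetas: np.ndarray,
    curve: np.ndarray,
    flat_threshold: float = 0.5,
) -> OrientationEstimate:
    """Estimate a particle's axis angle from its contrast-magnitude curve.

    The estimate is the filter angle of maximum |C|, reported modulo 90°
    (into [−45°, 45°)) because the two-fold rod symmetry makes orientations
    90° apart indistinguishable.  A flat curve (modulation depth below
    ``flat_threshold``) yields an explicit no-orientation result.
    """
    curve = np.asarray(curve, dtype=float)
    mag = np.abs(curve)
    if np.all(np.isnan(mag)):
        return OrientationEstimate(alpha_deg=None, modulation_depth=np.nan)
    mx, mn = np.nanmax(mag), np.nanmin(mag)
    depth = float((mx - mn) / mx) if mx > 0 else 0.0
    if depth < flat_threshold:
        return OrientationEstimate(alpha_deg=None, modulation_depth=depth)
    alpha = float(thetas[int(np.nanargmax(mag))])
    alpha = (alpha + 45.0) % 90.0 - 45.0
    return OrientationEstimate(alpha_deg=alpha, modulation_depth=depth)
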