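"""Scalar Fourier-optics engine.

Sampling grids, complex scalar fields, unitary sample/pupil transforms, the
hard-aperture pupil with paraxial defocus, and amplitude-PSF synthesis.

Conventions
-----------
* Real-space positions are in micrometres measured from the field-of-view
  corner; the optical axis pierces the array at index ``n // 2`` on each axis.
* Spatial frequencies are sample-plane frequencies in cycles per micrometre,
  DC-centred (DC at index ``n // 2``).
* All plane transforms use the unitary (``norm="ortho"``) DFT so total energy
  is preserved (Parseval).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "Plane",
    "GridSpec",
    "ComplexField",
    "make_grid",
    "to_pupil",
    "to_image",
    "pupil_function",
    "psf",
    "fit_psf_sigma",
    "calibrate_effective_na",
    "CALIBRATED_EFFECTIVE_NA",
    "PSF_SIGMA_UM",
]

#: Measured width of the instrument point spread function: the standard
#: deviation of a least-squares Gaussian fit to the intensity PSF, in μm.
PSF_SIGMA_UM = 0.61

#: Effective numerical aperture calibrated so that the Gaussian fit to the
#: simulated |PSF|^2 radial profile has sigma = PSF_SIGMA_UM at 640 nm.
#: Obtained from :func:`calibrate_effective_na`; see docs/methods.md.
CALIBRATED_EFFECTIVE_NA = 0.2196


class Plane(str, enum.Enum):
    """Which optical plane a :class:`ComplexField` lives in."""

    SAMPLE = "sample"
    PUPIL = "pupil"
    IMAGE = "image"


@dataclass(frozen=True)
class GridSpec:
    """Sampling geometry linking sample-plane coordinates to pupil frequencies.

    Parameters
    ----------
    n : int
        Pixels per side; must be a power of two >= 64.
    pixel_size : float
        Sample-plane pixel pitch in μm.
    wavelength : float
        Illumination wavelength in μm (default 0.640, red diode laser).
    na : float
        Physical numerical aperture of the objective (default 1.40).
    effective_na : float
        Radius of the hard pupil aperture expressed as an NA.  This is the
        PSF-width calibration knob: real instruments image wider spots than
        the diffraction limit, so the simulated aperture is shrunk until the
        fitted PSF width matches the measured one.
    """

    n: int
    pixel_size: float
    wavelength: float = 0.640
    na: float = 1.40
    effective_na: float = CALIBRATED_EFFECTIVE_NA

    def __post_init__(self) -> None:
        if self.n < 64 or (self.n & (self.n - 1)) != 0:
            raise ValueError(f"n must be a power of two >= 64, got {self.n}")
        if self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_size and wavelength must be positive")
        if self.effective_na > self.na:
            raise ValueError(
                f"unphysical pupil: effective_na {self.effective_na} exceeds "
                f"objective NA {self.na}"
            )
        if self.nu_na >= self.nyquist:
            raise ValueError(
                f"undersampled pupil: cutoff {self.nu_na:.3f} cycles/um is not "
                f"below Nyquist {self.nyquist:.3f} cycles/um"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def extent(self) -> float:
        """Field-of-view side length in μm."""
        return self.n * self.pixel_size

    @property
    def freq_step(self) -> float:
        """Frequency step Δν = 1/(n·pixel_size) in cycles/μm."""
        return 1.0 / (self.n * self.pixel_size)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2·pixel_size) in cycles/μm."""
        return 1.0 / (2.0 * self.pixel_size)

    @property
    def nu_na(self) -> float:
        """Pupil cutoff frequency effective_na/λ in cycles/μm."""
        return self.effective_na / self.wavelength

    @property
    def center(self) -> float:
        """Position of the optical axis in μm from the FOV corner."""
        return (self.n // 2) * self.pixel_size

    # -- coordinate arrays --------------------------------------------------

    def positions(self) -> np.ndarray:
        """1-D pixel-centre positions in μm from the FOV corner."""
        return np.arange(self.n) * self.pixel_size

    def freqs(self) -> np.ndarray:
        """1-D DC-centred frequency axis in cycles/μm."""
        return np.fft.fftshift(np.fft.fftfreq(self.n, d=self.pixel_size))

    def freq_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D (nu_x, nu_y) meshgrids, DC at index n//2."""
        nu = self.freqs()
        return np.meshgrid(nu, nu)

    def freq_radius(self) -> np.ndarray:
        """2-D |ν| in cycles/μm."""
        nx, ny = self.freq_grids()
        return np.hypot(nx, ny)


@dataclass
class ComplexField:
    """A square 2-D complex scalar amplitude tied to a grid and a plane."""

    values: np.ndarray
    plane: Plane
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError(
                f"field shape {self.values.shape} does not match grid n={self.grid.n}"
            )
        self.plane = Plane(self.plane)

    def energy(self) -> float:
        """Total energy Σ|values|²."""
        return float(np.sum(np.abs(self.values) ** 2))

    def copy(self) -> "ComplexField":
        return ComplexField(self.values.copy(), self.plane, self.grid)


def make_grid(
    n: int,
    pixel_size: float,
    wavelength: float = 0.640,
    na: float = 1.40,
    effective_na: float | None = None,
) -> GridSpec:
    """Build a :class:`GridSpec`, defaulting ``effective_na`` to the physical NA."""
    if effective_na is None:
        effective_na = na
    return GridSpec(
        n=n,
        pixel_size=pixel_size,
        wavelength=wavelength,
        na=na,
        effective_na=effective_na,
    )


# ---------------------------------------------------------------------------
# Plane transforms
# ---------------------------------------------------------------------------


def _fft2c(values: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(values), norm="ortho"))


def _ifft2c(values: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(values), norm="ortho"))


def to_pupil(field: ComplexField) -> ComplexField:
    """Transform a sample- or image-plane field to the pupil (Fourier) plane.

    Unitary DC-centred DFT: a unit impulse at the grid centre maps to a
    constant-magnitude pupil, and energy is preserved exactly.
    """
    if field.plane not in (Plane.SAMPLE, Plane.IMAGE):
        raise ValueError(f"to_pupil expects a sample or image field, got {field.plane}")
    return ComplexField(_fft2c(field.values), Plane.PUPIL, field.grid)


def to_image(field: ComplexField) -> ComplexField:
    """Inverse of :func:`to_pupil`: pupil plane back to the image plane."""
    if field.plane is not Plane.PUPIL:
        raise ValueError(f"to_image expects a pupil field, got {field.plane}")
    return ComplexField(_ifft2c(field.values), Plane.IMAGE, field.grid)


# ---------------------------------------------------------------------------
# Pupil and PSF
# ---------------------------------------------------------------------------


def aperture_mask(grid: GridSpec) -> np.ndarray:
    """Boolean hard circular aperture |ν| <= ν_NA."""
    return grid.freq_radius() <= grid.nu_na


def defocus_phase(grid: GridSpec, defocus_z: float) -> np.ndarray:
    """Paraxial defocus phasor exp(i·π·λ·z·|ν|²) over the full grid."""
    r2 = grid.freq_radius() ** 2
    return np.exp(1j * np.pi * grid.wavelength * defocus_z * r2)


def pupil_function(grid: GridSpec, defocus_z: float = 0.0) -> ComplexField:
    """Hard circular aperture times the paraxial defocus phase.

    At ``defocus_z = 0`` every passed value is exactly 1; the defocus factor
    is phase-only, so PSF energy is independent of z.
    """
    values = aperture_mask(grid).astype(complex)
    if defocus_z != 0.0:
        values *= defocus_phase(grid, defocus_z)
        values[~aperture_mask(grid)] = 0.0
    return ComplexField(values, Plane.PUPIL, grid)


def psf(grid: GridSpec, defocus_z: float = 0.0) -> ComplexField:
    """Amplitude point-spread function: the image of the pupil function.

    Peak is centred at grid index (n//2, n//2) for zero defocus.
    """
    return to_image(pupil_function(grid, defocus_z))


def psf_peak_amplitude(grid: GridSpec) -> float:
    """In-focus amplitude-PSF value at the grid centre (real, positive).

    Used to normalise scattered fields so a scatterer of amplitude ``s``
    interferes with the reference at relative amplitude ``s``.
    """
    c = grid.n // 2
    return float(psf(grid).values[c, c].real)


# ---------------------------------------------------------------------------
# PSF-width calibration
# ---------------------------------------------------------------------------


def radial_profile(
    image: np.ndarray,
    pixel_size: float,
    r_max: float,
    n_bins: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged radial profile about the array centre.

    Returns (bin-centre radii in μm, mean value per bin).  Empty bins are
    dropped.
    """
    n = image.shape[0]
    x = (np.arange(n) - n // 2) * pixel_size
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy).ravel()
    v = np.asarray(image, dtype=float).ravel()
    sel = r < r_max
    bins = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.digitize(r[sel], bins) - 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v[sel], minlength=n_bins)
    keep = counts > 0
    centres = 0.5 * (bins[:-1] + bins[1:])
    return centres[keep], sums[keep] / counts[keep]


def fit_psf_sigma(grid: GridSpec, defocus_z: float = 0.0, r_max: float = 4.0) -> float:
    """Gaussian width of the intensity PSF.

    Least-squares fit of ``A·exp(-r²/(2σ²))`` to the azimuthally averaged
    radial profile of |PSF|²; returns σ in μm.
    """
    intensity = np.abs(psf(grid, defocus_z).values) ** 2
    r, prof = radial_profile(intensity, grid.pixel_size, r_max=r_max)

    def gauss(rr: np.ndarray, amp: float, sigma: float) -> np.ndarray:
        return amp * np.exp(-(rr**2) / (2.0 * sigma**2))

    sigma0 = max(0.21 * grid.wavelength / grid.effective_na, grid.pixel_size)
    popt, _ = curve_fit(gauss, r, prof, p0=[prof[0], sigma0], maxfev=10000)
    return abs(float(popt[1]))


def calibrate_effective_na(
    target_sigma: float = PSF_SIGMA_UM,
    wavelength: float = 0.640,
    na: float = 1.40,
    n: int = 1024,
    pixel_size: float = 0.1,
    bracket: tuple[float, float] = (0.1, 1.2),
) -> float:
    """Solve for the effective NA whose fitted PSF sigma equals ``target_sigma``.

    Uses a bracketing root find on :func:`fit_psf_sigma`; the fitted sigma of a
    hard-aperture Airy intensity scales as ~0.28·λ/NA, so the map is monotone.
    """

    def residual(na_eff: float) -> float:
        grid = GridSpec(
            n=n, pixel_size=pixel_size, wavelength=wavelength, na=na, effective_na=na_eff
        )
        return fit_psf_sigma(grid) - target_sigma

    return float(brentq(residual, *bracket, xtol=1e-4))
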