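"""Synthetic complex refractive-index spectra from Lorentz band lists.

A material's "chemistry" is described generatively by a set of Lorentz
absorption bands plus a constant real-index offset.  The imaginary part
k(nu) is a sum of amplitude-normalized Lorentzians; the fluctuating real
part is obtained from k via the Kramers-Kronig (Hilbert-transform)
relation, so the generated complex index m(nu) = n(nu) + i k(nu) is
causal.  A closed-form complex Lorentz-oscillator sum is provided as an
independent analytic oracle for the numerical transform.

Units: wavenumbers nu in cm^-1 throughout; n, k dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "LorentzBand",
    "ChemistryModel",
    "RefractiveIndexSpectrum",
    "default_chemistry",
    "default_grid",
    "synth_imag_index",
    "kk_real_index",
    "lorentz_complex_analytic",
    "shift_bands",
    "synthesize",
]


@dataclass(frozen=True)
class LorentzBand:
    """One Lorentzian absorption band.

    Parameters
    ----------
    center : float
        Band center (cm^-1), > 0.
    width : float
        Full width at half maximum (cm^-1), > 0.
    amplitude : float
        Peak value of the imaginary index k at the band center, >= 0.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ValueError(f"band center must be > 0, got {self.center}")
        if not self.width > 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class ChemistryModel:
    """A set of Lorentz bands plus a constant real-index offset."""

    bands: tuple[LorentzBand, ...]
    n_offset: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.n_offset > 1:
            raise ValueError(f"n_offset must be > 1, got {self.n_offset}")
        centers = [b.center for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")

    def with_offset(self, n_offset: float) -> "ChemistryModel":
        return ChemistryModel(self.bands, n_offset)


@dataclass(frozen=True)
class RefractiveIndexSpectrum:
    """Complex refractive index m(nu) = n(nu) + i k(nu) on a wavenumber grid."""

    grid: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if not (grid.shape == n.shape == k.shape) or grid.ndim != 1:
            raise ValueError("grid, n, k must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(k < -1e-12):
            raise ValueError("imaginary index k must be non-negative")
        if np.any(n <= 0):
            raise ValueError("real index n must be positive")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def m(self) -> np.ndarray:
        """Complex index n + i k."""
        return self.n + 1j * self.k


# Band centers of the reference chemistry (cm^-1): the four bands whose
# positions the peak-shift control experiment displaces.
DEFAULT_BAND_CENTERS = (1500.0, 2010.0, 3000.0, 5400.0)
DEFAULT_BAND_WIDTH = 60.0
DEFAULT_BAND_AMPLITUDE = 0.1


def default_chemistry(
    width: float = DEFAULT_BAND_WIDTH,
    amplitude: float = DEFAULT_BAND_AMPLITUDE,
    n_offset: float = 1.5,
) -> ChemistryModel:
    """Reference four-band chemistry (1500, 2010, 3000, 5400 cm^-1)."""
    bands = tuple(LorentzBand(c, width, amplitude) for c in DEFAULT_BAND_CENTERS)
    return ChemistryModel(bands, n_offset)


def default_grid(start: float = 1000.0, stop: float = 6000.0, step: float = 2.0) -> np.ndarray:
    """Uniform wavenumber grid, inclusive of both endpoints."""
    npts = int(round((stop - start) / step)) + 1
    return start + step * np.arange(npts)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    return grid


def synth_imag_index(chem: ChemistryModel, grid: np.ndarray) -> np.ndarray:
    """Imaginary index k(nu): sum of amplitude-normalized Lorentzians.

    Each band contributes amplitude * (w/2)^2 / ((nu - c)^2 + (w/2)^2),
    so k(center) = amplitude and k(center +/- w/2) = amplitude/2.
    Bands centered outside the grid raise a warning but are still evaluated
    (their wings contribute).
    """
    grid = _check_grid(grid)
    k = np.zeros_like(grid)
    for band in chem.bands:
        if band.center < grid[0] or band.center > grid[-1]:
            warnings.warn(
                f"band at {band.center} cm^-1 lies outside grid "
                f"[{grid[0]}, {grid[-1]}]; its wings are still evaluated",
                stacklevel=2,
            )
        hw = band.width / 2.0
        k += band.amplitude * hw**2 / ((grid - band.center) ** 2 + hw**2)
    return k


def _uniform_spacing(grid: np.ndarray) -> float:
    d = np.diff(grid)
    h = d[0]
    if not np.allclose(d, h, rtol=1e-8, atol=0.0):
        raise ValueError("kk_real_index requires a uniformly spaced grid; resample first")
    return float(h)


def kk_real_index(
    k: np.ndarray, grid: np.ndarray, n_offset: float = 1.5, guard_frac: float = 0.2
) -> np.ndarray:
    """Real index n(nu) from k(nu) via the Kramers-Kronig relation.

    Evaluates the Hilbert-transform dispersion relation

        n(nu) = n_offset + (1/pi) P-int k(nu') / (nu' - nu) dnu'

    with the Maclaurin (alternating-point) principal-value rule: the sum at
    grid point i runs only over points j with j - i odd, which steps over
    the singularity without special handling.  The grid is extended by
    ``guard_frac`` of its span with zeros on both sides to curb truncation
    error.  Far from all bands n -> n_offset.
    """
    grid = _check_grid(grid)
    k = np.asarray(k, dtype=float)
    if k.shape != grid.shape:
        raise ValueError("k and grid must have equal length")
    h = _uniform_spacing(grid)

    nguard = int(np.ceil(guard_frac * grid.size))
    kp = np.concatenate([np.zeros(nguard), k, np.zeros(nguard)])
    npad = kp.size

    # Maclaurin sum is a discrete convolution with kernel 1/(m*h) on odd
    # offsets m: n_i = n_offset + (2h/pi) * sum_{j-i odd} k_j / (nu_j - nu_i).
    offsets = np.arange(-(npad - 1), npad)
    kernel = np.where(offsets % 2 != 0, 1.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = np.where(kernel > 0, 1.0 / (offsets * h), 0.0)
    # convolve(k, kernel)[i] = sum_j k_j * kernel[i - j]; we need
    # sum_j k_j / (nu_j - nu_i) = sum_j k_j * 1/((j - i) h), i.e. the
    # correlation; flip the kernel (it is odd, so this is a sign flip).
    hsum = fftconvolve(kp, kernel[::-1], mode="same")
    n = n_offset + (2.0 * h / np.pi) * hsum[nguard : nguard + grid.size]
    return n


def lorentz_complex_analytic(chem: ChemistryModel, grid: np.ndarray) -> RefractiveIndexSpectrum:
    """Closed-form complex Lorentzian index: the analytic KK oracle.

    Each band contributes the one-pole complex Lorentzian

        a * (w/2) / (c - nu - i*(w/2)),

    whose imaginary part is exactly the profile of :func:`synth_imag_index`
    and whose real part is its exact Hilbert transform (the pole lies in
    the lower half plane, so the function is causal).  Used to validate the
    numerical KK transform; exhibits anomalous dispersion (n > n_offset on
    the low-wavenumber side of each band).
    """
    grid = _check_grid(grid)
    chi = np.zeros(grid.size, dtype=complex)
    for band in chem.bands:
        hw = band.width / 2.0
        chi += band.amplitude * hw / (band.center - grid - 1j * hw)
    n = chem.n_offset + chi.real
    return RefractiveIndexSpectrum(grid=grid, n=n, k=chi.imag)


def shift_bands(chem: ChemistryModel, mapping: dict[float, float]) -> ChemistryModel:
    """Move band centers according to ``mapping`` (old center -> new center).

    Widths and amplitudes are preserved; bands are re-sorted by center.
    Every key must match an existing band center exactly.
    """
    centers = [b.center for b in chem.bands]
    for old in mapping:
        if old not in centers:
            raise ValueError(f"no band with center {old} cm^-1 in chemistry")
    moved = [
        LorentzBand(mapping.get(b.center, b.center), b.width, b.amplitude) for b in chem.bands
    ]
    moved.sort(key=lambda b: b.center)
    return ChemistryModel(tuple(moved), chem.n_offset)


# Peak displacement used by the negative-control experiment (cm^-1).
PEAK_SHIFT_MAPPING = {1500.0: 1520.0, 2010.0: 1950.0, 3000.0: 3500.0, 5400.0: 5350.0}


def synthesize(chem: ChemistryModel, grid: np.ndarray) -> RefractiveIndexSpectrum:
    """Full synthetic index: Lorentzian k plus KK-consistent real part."""
    grid = _check_grid(grid)
    k = synth_imag_index(chem, grid)
    n = kk_real_index(k, grid, chem.n_offset)
    return RefractiveIndexSpectrum(grid=grid, n=n, k=k)
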