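"""Extinction efficiencies Q_ext for sphere, dome, semi-cylinder, semi-capsule.

Three routes to Q_ext are provided:

* closed-form anomalous-diffraction (van de Hulst) models, in which the
  incident ray traverses the scatterer straight through and acquires only
  the phase shift of the local chord length;
* a numerical straight-ray quadrature oracle (the same physics integrated
  adaptively over the projected cross section), the arbiter of correctness
  for the closed forms;
* the exact Mie series for the homogeneous sphere.

Geometry convention: the dome (hemisphere flat-face-down on a substrate)
and the semi-capsule (dome elongated by a half-cylinder mid-section of
length L between two quarter-sphere end caps) are illuminated along the
dome axis, normal to the flat face.  Under straight-ray propagation the
chord through a dome is half the chord through the parent sphere, so the
dome curve is exactly the sphere curve at half the phase parameter.

Units: wavenumber nu in cm^-1, radius R and elongation L in micrometres
(converted internally, R[cm] = R[um] * 1e-4).  Size parameter
x = 2*pi*nu*R[cm]; complex phase parameter rho = 2x(m-1).

Sign convention: time dependence e^{-i omega t}, so absorbing media have
Im(m) = k >= 0 and the transmitted-ray factor is e^{+i k0 (m-1) t}, which
decays for k > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Union

import numpy as np
from mpmath import besselj as _mp_besselj
from mpmath import struveh as _mp_struveh
from scipy import integrate

from .refindex import RefractiveIndexSpectrum

__all__ = [
    "ScattererGeometry",
    "ExtinctionSpectrum",
    "ApertureGeometry",
    "AbsorbanceSpectrum",
    "qext_vdh_sphere",
    "qext_dome",
    "qext_semicylinder",
    "qext_semicapsule",
    "qext_ada_numeric",
    "ada_qext_radial",
    "ada_qext_strip",
    "qext_mie_exact",
    "absorbance_from_qext",
    "first_wiggle_maximum",
]

UM_TO_CM = 1e-4

Shape = Literal["sphere", "dome", "semi-cylinder", "semi-capsule"]


@dataclass(frozen=True)
class ScattererGeometry:
    """Scatterer shape with end-cap/base radius R (um) and elongation L (um)."""

    shape: Shape
    R: float
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "dome", "semi-cylinder", "semi-capsule"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not self.R > 0:
            raise ValueError("R must be positive")
        if self.L < 0:
            raise ValueError("L must be non-negative")
        if self.L > 0 and self.shape != "semi-capsule":
            raise ValueError("elongation L applies to semi-capsules only")


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Q_ext(nu) with geometry and method provenance."""

    grid: np.ndarray
    qext: np.ndarray
    geometry: ScattererGeometry
    method: Literal["vdh-closed-form", "ada-numeric", "mie-exact"]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        q = np.asarray(self.qext, dtype=float)
        if grid.shape != q.shape or grid.ndim != 1:
            raise ValueError("grid and qext must be 1-D arrays of equal length")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "qext", q)

    def size_parameter(self) -> np.ndarray:
        """x = 2*pi*nu*R per grid point."""
        return 2.0 * np.pi * self.grid * self.geometry.R * UM_TO_CM


@dataclass(frozen=True)
class ApertureGeometry:
    """Sample (g) and detector/aperture (G) geometric cross sections, um^2."""

    g: float
    G: float

    def __post_init__(self) -> None:
        if not (0 < self.g < self.G):
            raise ValueError("aperture model requires 0 < g < G")


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Apparent absorbance Z(nu), with the approximation route flagged."""

    grid: np.ndarray
    z: np.ndarray
    linearized: bool


def _complex_index(m: Union[RefractiveIndexSpectrum, complex, float], grid: np.ndarray) -> np.ndarray:
    """Complex index per grid point from a spectrum or a scalar."""
    if isinstance(m, RefractiveIndexSpectrum):
        if m.grid.shape != grid.shape or not np.allclose(m.grid, grid, rtol=0, atol=1e-9):
            raise ValueError("refractive-index spectrum is not defined on the requested grid")
        return m.m
    mc = complex(m)
    if mc.imag < 0:
        raise ValueError("imaginary index must be non-negative (e^{-i omega t} convention)")
    return np.full(np.asarray(grid).shape, mc, dtype=complex)


def _check_positive_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("wavenumbers must be positive")
    return grid


def _warn_if_n_below_one(mvals: np.ndarray) -> None:
    if np.any(mvals.real < 1):
        warnings.warn("real index n < 1 encountered; formulas remain defined", stacklevel=3)


def _vdh_from_a(a: np.ndarray) -> np.ndarray:
    """van de Hulst kernel Q = 4*Re{1/2 + e^{-a}/a - (1 - e^{-a})/a^2}.

    a = -i*rho with complex phase parameter rho; Re(a) >= 0 for absorbing
    media.  The a -> 0 limit is 0; small |a| handled by series to avoid
    cancellation.
    """
    a = np.asarray(a, dtype=complex)
    out = np.empty(a.shape, dtype=float)
    small = np.abs(a) < 1e-4
    asml = a[small]
    # series of the bracket: a/3 - a^2/8 + a^3/30 - ... (leading terms)
    out[small] = 4.0 * (asml / 3.0 - asml**2 / 8.0 + asml**3 / 30.0).real
    alrg = a[~small]
    ea = np.exp(-alrg)
    out[~small] = 4.0 * (0.5 + ea / alrg - (1.0 - ea) / alrg**2).real
    return out


def qext_vdh_sphere(
    m: Union[RefractiveIndexSpectrum, complex, float], R: float, grid: np.ndarray
) -> ExtinctionSpectrum:
    """Anomalous-diffraction Q_ext of a sphere of radius R (um).

    Chord t(r) = 2*sqrt(R^2 - r^2) over the projected disk gives the
    classic van de Hulst form with complex phase rho = 2x(m-1); for
    non-absorbing media it reduces to
    Q = 2 - (4/rho) sin(rho) + (4/rho^2)(1 - cos(rho)).
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    _warn_if_n_below_one(mv)
    x = 2.0 * np.pi * grid * R * UM_TO_CM
    rho = 2.0 * x * (mv - 1.0)
    q = _vdh_from_a(-1j * rho)
    return ExtinctionSpectrum(grid, q, ScattererGeometry("sphere", R), "vdh-closed-form")


def qext_dome(
    m: Union[RefractiveIndexSpectrum, complex, float], R: float, grid: np.ndarray
) -> ExtinctionSpectrum:
    """Anomalous-diffraction Q_ext of a dome (hemisphere, axis illumination).

    The chord t(r) = sqrt(R^2 - r^2) is half the sphere chord, so the dome
    curve equals the sphere curve at half the phase parameter (the factor-2
    reduced path length).
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    _warn_if_n_below_one(mv)
    x = 2.0 * np.pi * grid * R * UM_TO_CM
    rho = 2.0 * x * (mv - 1.0)
    q = _vdh_from_a(-1j * rho / 2.0)
    return ExtinctionSpectrum(grid, q, ScattererGeometry("dome", R), "vdh-closed-form")


def _struve_h1(z: np.ndarray) -> np.ndarray:
    """Struve H_1 for complex argument (vectorized over mpmath)."""
    flat = np.asarray(z, dtype=complex).ravel()
    out = np.array([complex(_mp_struveh(1, complex(v))) for v in flat])
    return out.reshape(np.shape(z))


def _besselj1(z: np.ndarray) -> np.ndarray:
    flat = np.asarray(z, dtype=complex).ravel()
    out = np.array([complex(_mp_besselj(1, complex(v))) for v in flat])
    return out.reshape(np.shape(z))


def qext_semicylinder(
    m: Union[RefractiveIndexSpectrum, complex, float], R: float, grid: np.ndarray
) -> ExtinctionSpectrum:
    """Anomalous-diffraction Q_ext of an infinitely long semi-cylinder.

    Normal incidence on the flat face; per-length normalization by the
    projected width 2R.  The chord integral over t(y) = sqrt(R^2 - y^2)
    evaluates in closed form via Struve and Bessel functions:

        Q = Re{ pi H_1(c) - i pi J_1(c) },   c = x (m - 1).
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    _warn_if_n_below_one(mv)
    x = 2.0 * np.pi * grid * R * UM_TO_CM
    c = x * (mv - 1.0)
    q = (np.pi * _struve_h1(c) - 1j * np.pi * _besselj1(c)).real
    return ExtinctionSpectrum(grid, q, ScattererGeometry("semi-cylinder", R), "vdh-closed-form")


def qext_semicapsule(
    m: Union[RefractiveIndexSpectrum, complex, float], R: float, L: float, grid: np.ndarray
) -> ExtinctionSpectrum:
    """Anomalous-diffraction Q_ext of a semi-capsule (elongated dome).

    The projection is a stadium: a disk of radius R (the two quarter-sphere
    end caps seen from above form a full dome disk) plus a 2R x L rectangle
    over the half-cylinder mid-section.  Because the ADA integral is linear
    over disjoint projection regions, Q_ext is the projected-area-weighted
    mix of the dome and semi-cylinder efficiencies:

        Q = (pi R^2 Q_dome + 2 R L Q_semicyl) / (pi R^2 + 2 R L).

    L = 0 degenerates exactly to the dome.
    """
    if L < 0:
        raise ValueError("elongation L must be non-negative")
    grid = _check_positive_grid(grid)
    qd = qext_dome(m, R, grid).qext
    if L == 0:
        q = qd
    else:
        qc = qext_semicylinder(m, R, grid).qext
        a_disk = np.pi * R**2
        a_rect = 2.0 * R * L
        q = (a_disk * qd + a_rect * qc) / (a_disk + a_rect)
    return ExtinctionSpectrum(grid, q, ScattererGeometry("semi-capsule", R, L), "vdh-closed-form")


def qext(
    geometry: ScattererGeometry,
    m: Union[RefractiveIndexSpectrum, complex, float],
    grid: np.ndarray,
) -> ExtinctionSpectrum:
    """Closed-form ADA Q_ext dispatched on geometry."""
    if geometry.shape == "sphere":
        return qext_vdh_sphere(m, geometry.R, grid)
    if geometry.shape == "dome":
        return qext_dome(m, geometry.R, grid)
    if geometry.shape == "semi-cylinder":
        return qext_semicylinder(m, geometry.R, grid)
    return qext_semicapsule(m, geometry.R, geometry.L, grid)


# ---------------------------------------------------------------------------
# Numerical straight-ray (ADA) quadrature oracles
# ---------------------------------------------------------------------------


def _ada_integrand(t: np.ndarray, k0: float, mval: complex) -> np.ndarray:
    """2*Re{1 - e^{+i k0 (m-1) t}} for chord length t (cm)."""
    return 2.0 * (1.0 - np.exp(1j * k0 * (mval - 1.0) * t)).real


def ada_qext_radial(
    chord: Callable[[np.ndarray], np.ndarray],
    R: float,
    m: Union[RefractiveIndexSpectrum, complex, float],
    grid: np.ndarray,
    tol: float = 1e-10,
) -> ExtinctionSpectrum:
    """ADA oracle for an axially symmetric projection (disk of radius R, um).

    ``chord(r)`` gives the chord length in um at projected radius r in um.
    Q(nu) = (1/(pi R^2)) * int_0^R 2 Re{1 - e^{i k0 (m-1) t(r)}} 2 pi r dr,
    by adaptive quadrature per grid point.
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    q = np.empty(grid.shape)
    for i, (nu, mval) in enumerate(zip(grid, mv)):
        k0 = 2.0 * np.pi * nu

        def f(r: float) -> float:
            t_cm = chord(r) * UM_TO_CM
            return _ada_integrand(t_cm, k0, mval) * 2.0 * r

        val, err = integrate.quad(f, 0.0, R, epsabs=tol * R**2, epsrel=tol, limit=400)
        if err > max(100 * tol * R**2, 1e-8 * R**2):
            raise RuntimeError(
                f"radial ADA quadrature did not converge at nu={nu}: estimate {val}, error {err}"
            )
        q[i] = val / R**2
    return ExtinctionSpectrum(
        grid, q, ScattererGeometry("sphere", R), "ada-numeric"
    )


def ada_qext_strip(
    chord: Callable[[np.ndarray], np.ndarray],
    halfwidth: float,
    m: Union[RefractiveIndexSpectrum, complex, float],
    grid: np.ndarray,
    tol: float = 1e-10,
) -> ExtinctionSpectrum:
    """ADA oracle for a translationally invariant projection (strip, per length).

    ``chord(y)`` gives the chord length in um at transverse offset y; the
    efficiency is normalized by the projected width 2*halfwidth.
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    b = halfwidth
    q = np.empty(grid.shape)
    for i, (nu, mval) in enumerate(zip(grid, mv)):
        k0 = 2.0 * np.pi * nu

        def f(y: float) -> float:
            return _ada_integrand(chord(y) * UM_TO_CM, k0, mval)

        val, err = integrate.quad(f, -b, b, epsabs=tol * 2 * b, epsrel=tol, limit=400)
        if err > max(100 * tol * 2 * b, 1e-8 * b):
            raise RuntimeError(
                f"strip ADA quadrature did not converge at nu={nu}: estimate {val}, error {err}"
            )
        q[i] = val / (2.0 * b)
    return ExtinctionSpectrum(
        grid, q, ScattererGeometry("semi-cylinder", halfwidth), "ada-numeric"
    )


def qext_ada_numeric(
    geometry: ScattererGeometry,
    m: Union[RefractiveIndexSpectrum, complex, float],
    grid: np.ndarray,
    tol: float = 1e-10,
) -> ExtinctionSpectrum:
    """Numerical ADA Q_ext for a named geometry (the brute-force oracle).

    Integrates the straight-ray interference integrand over the projected
    cross section by adaptive quadrature, exploiting the symmetry of each
    projection (radial integral for disks, transverse integral for strips,
    area-weighted disjoint union for the stadium).  Serves as the
    independent check on every closed form.
    """
    R = geometry.R
    if geometry.shape == "sphere":
        out = ada_qext_radial(lambda r: 2.0 * np.sqrt(np.maximum(R**2 - r**2, 0.0)), R, m, grid, tol)
    elif geometry.shape == "dome":
        out = ada_qext_radial(lambda r: np.sqrt(np.maximum(R**2 - r**2, 0.0)), R, m, grid, tol)
    elif geometry.shape == "semi-cylinder":
        out = ada_qext_strip(lambda y: np.sqrt(np.maximum(R**2 - y**2, 0.0)), R, m, grid, tol)
    else:
        qd = ada_qext_radial(
            lambda r: np.sqrt(np.maximum(R**2 - r**2, 0.0)), R, m, grid, tol
        ).qext
        if geometry.L == 0:
            q = qd
        else:
            qc = ada_qext_strip(
                lambda y: np.sqrt(np.maximum(R**2 - y**2, 0.0)), R, m, grid, tol
            ).qext
            a_disk, a_rect = np.pi * R**2, 2.0 * R * geometry.L
            q = (a_disk * qd + a_rect * qc) / (a_disk + a_rect)
        return ExtinctionSpectrum(grid, q, geometry, "ada-numeric")
    return ExtinctionSpectrum(np.asarray(grid, dtype=float), out.qext, geometry, "ada-numeric")


def qext_ada_area(
    chord: Callable[[float, float], float],
    xbounds: tuple[float, float],
    ybounds: tuple[float, float],
    area: float,
    m: Union[RefractiveIndexSpectrum, complex, float],
    grid: np.ndarray,
    tol: float = 1e-9,
) -> ExtinctionSpectrum:
    """Fully general 2-D ADA quadrature over a rectangle-bounded region.

    ``chord(x, y)`` must return 0 outside the projected region; ``area`` is
    the region's projected area (um^2).  Slow (adaptive dblquad per grid
    point); intended for spot checks of the symmetry-reduced oracles.
    """
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    q = np.empty(grid.shape)
    for i, (nu, mval) in enumerate(zip(grid, mv)):
        k0 = 2.0 * np.pi * nu

        def f(y: float, x: float) -> float:
            t = chord(x, y)
            if t <= 0.0:
                return 0.0
            return float(_ada_integrand(t * UM_TO_CM, k0, mval))

        val, err = integrate.dblquad(
            f, xbounds[0], xbounds[1], ybounds[0], ybounds[1], epsabs=tol * area, epsrel=tol
        )
        q[i] = val / area
    return ExtinctionSpectrum(
        grid, q, ScattererGeometry("sphere", max(abs(xbounds[1]), 1.0)), "ada-numeric"
    )


# ---------------------------------------------------------------------------
# Exact Mie series for the homogeneous sphere
# ---------------------------------------------------------------------------


def _mie_qext_single(mval: complex, x: float) -> float:
    """Mie extinction efficiency for one size parameter.

    Series truncated at the Wiscombe order nmax = x + 4 x^(1/3) + 2; the
    logarithmic derivative D_n(mx) is generated by downward recurrence
    starting 15 orders above nmax.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = nmax + 15
    mx = mval * x

    d = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence (stable for
    # the orders retained, n <= x + O(x^{1/3})).
    n_arr = np.arange(1, nmax + 1)
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi_0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi_0 = -np.sin(x), np.cos(x)
    psi[0], chi[0] = psi_0, chi_0
    pm2, pm1 = psi_m1, psi_0
    cm2, cm1 = chi_m1, chi_0
    for n in range(1, nmax + 1):
        pn = (2 * n - 1) / x * pm1 - pm2
        cn = (2 * n - 1) / x * cm1 - cm2
        if n <= nmax:
            psi[n] = pn
            chi[n] = cn
        pm2, pm1 = pm1, pn
        cm2, cm1 = cm1, cn
    if not np.all(np.isfinite(psi)) or not np.all(np.isfinite(chi)):
        raise OverflowError(f"Riccati-Bessel recurrence overflowed at x={x}")

    xi = psi - 1j * chi
    dn = d[1 : nmax + 1]
    an_num = (dn / mval + n_arr / x) * psi[1:] - psi[:-1]
    an_den = (dn / mval + n_arr / x) * xi[1:] - xi[:-1]
    bn_num = (dn * mval + n_arr / x) * psi[1:] - psi[:-1]
    bn_den = (dn * mval + n_arr / x) * xi[1:] - xi[:-1]
    an = an_num / an_den
    bn = bn_num / bn_den
    qe = (2.0 / x**2) * np.sum((2 * n_arr + 1) * (an + bn).real)
    return float(qe)


def qext_mie_exact(
    m: Union[RefractiveIndexSpectrum, complex, float], R: float, grid: np.ndarray
) -> ExtinctionSpectrum:
    """Exact Mie-series Q_ext for a homogeneous sphere of radius R (um)."""
    grid = _check_positive_grid(grid)
    mv = _complex_index(m, grid)
    x = 2.0 * np.pi * grid * R * UM_TO_CM
    q = np.array([_mie_qext_single(mval, xi) for mval, xi in zip(mv, x)])
    return ExtinctionSpectrum(grid, q, ScattererGeometry("sphere", R), "mie-exact")


def rayleigh_qext(m: complex, x: np.ndarray) -> np.ndarray:
    """Small-particle (Rayleigh) limit (8/3) x^4 |(m^2-1)/(m^2+2)|^2."""
    x = np.asarray(x, dtype=float)
    pol = (m**2 - 1.0) / (m**2 + 2.0)
    return (8.0 / 3.0) * x**4 * np.abs(pol) ** 2


# ---------------------------------------------------------------------------
# Extinction -> apparent absorbance
# ---------------------------------------------------------------------------


def absorbance_from_qext(
    q: ExtinctionSpectrum, ap: ApertureGeometry, linearized: bool = False
) -> AbsorbanceSpectrum:
    """Apparent absorbance Z = -log10(1 - (g/G) Q_ext).

    With ``linearized=True`` returns the G >> g first-order form
    Z = (1/ln 10)(g/G) Q_ext instead; the flag is recorded on the output.
    """
    ratio = ap.g / ap.G
    arg = ratio * q.qext
    if np.any(arg >= 1.0):
        raise ValueError("(g/G) * Q_ext >= 1: total extinction exceeds the aperture model")
    if linearized:
        z = arg / np.log(10.0)
    else:
        z = -np.log10(1.0 - arg)
    return AbsorbanceSpectrum(grid=q.grid, z=z, linearized=linearized)


# ---------------------------------------------------------------------------
# Wiggle diagnostics
# ---------------------------------------------------------------------------


def first_wiggle_maximum(
    grid: np.ndarray,
    qext: np.ndarray,
    smooth_window: float | None = None,
    prominence_frac: float = 0.1,
) -> float:
    """Wavenumber of the first wiggle maximum of Q_ext within the grid.

    Wiggles are the broad interference oscillations; sharp shape-resonance
    ripples (present in exact Mie curves) are rejected by a prominence
    threshold, ``prominence_frac`` of the curve's range, and optionally by
    Savitzky-Golay pre-smoothing over ``smooth_window`` (cm^-1, should be
    wide versus the ripple spacing and narrow versus the wiggle period).
    The located peak is refined by parabolic interpolation.
    """
    from scipy.signal import find_peaks, savgol_filter

    grid = np.asarray(grid, dtype=float)
    q = np.asarray(qext, dtype=float)
    if smooth_window is not None:
        step = float(np.median(np.diff(grid)))
        npts = max(5, int(round(smooth_window / step)) | 1)  # odd
        q = savgol_filter(q, npts, 3)
    prominence = prominence_frac * (q.max() - q.min())
    peaks, _ = find_peaks(q, prominence=prominence)
    if peaks.size == 0:
        raise ValueError("no wiggle maximum found in Q_ext over this grid")
    i = int(peaks[0])
    denom = q[i - 1] - 2.0 * q[i] + q[i + 1]
    if denom == 0:
        return float(grid[i])
    delta = 0.5 * (q[i - 1] - q[i + 1]) / denom
    return float(grid[i] + delta * (grid[i + 1] - grid[i]))
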