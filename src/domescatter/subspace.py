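"""Sphere-subspace (ME-EMSC meta-model) reconstruction of deformed-sphere Q_ext.

The Mie-extinction EMSC preprocessing of infrared spectra models the
scattering contribution of a cell with a PCA-compressed set of van de
Hulst sphere extinction curves.  This module reproduces the core of that
meta-model and the experiment that validates it for substrate-deformed
(dome / semi-capsule shaped) cells: build a training set of sphere curves
spanning plausible real-index offsets and radii, compress by PCA, project
a semi-capsule extinction curve onto the retained components, and sweep
the number of components n_comp.  A peak-shift negative control verifies
that the subspace is chemistry-specific: curves computed from a chemistry
with displaced absorption bands cannot be reconstructed at the shifted
band positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import refindex
from .extinction import ExtinctionSpectrum, ScattererGeometry, qext_semicapsule, qext_vdh_sphere
from .refindex import ChemistryModel, RefractiveIndexSpectrum, kk_real_index, synth_imag_index

__all__ = [
    "TrainingGrid",
    "SubspaceBasis",
    "ReconstructionReport",
    "build_training_set",
    "fit_subspace",
    "reconstruct",
    "sweep_ncomp",
    "peak_shift_experiment",
    "band_windows",
]


@dataclass(frozen=True)
class TrainingGrid:
    """Real-index offsets and sphere radii spanned by the training curves."""

    offsets: tuple[float, ...]
    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        if any(not 1.0 < o for o in self.offsets):
            raise ValueError("offsets must exceed 1")
        if any(not r > 0 for r in self.radii):
            raise ValueError("radii must be positive")

    @property
    def n_curves(self) -> int:
        return len(self.offsets) * len(self.radii)

    @classmethod
    def default(cls) -> "TrainingGrid":
        """10 x 10 grid: offsets 1.3-1.7, radii 5-10 um (100 curves)."""
        return cls(tuple(np.linspace(1.3, 1.7, 10)), tuple(np.linspace(5.0, 10.0, 10)))


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal PCA basis of sphere extinction curves."""

    grid: np.ndarray
    mean_curve: np.ndarray
    components: np.ndarray  # (n_components, n_points), orthonormal rows
    explained_variance: np.ndarray  # non-increasing
    centered: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "mean_curve", np.asarray(self.mean_curve, dtype=float))
        object.__setattr__(self, "components", np.asarray(self.components, dtype=float))
        object.__setattr__(
            self, "explained_variance", np.asarray(self.explained_variance, dtype=float)
        )

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class ReconstructionReport:
    """Diagnostics of one projection onto the sphere subspace."""

    n_comp: int
    reconstructed: np.ndarray
    residual: np.ndarray  # original - reconstructed
    rel_rmse: float
    band_residuals: dict[str, float] = field(default_factory=dict)


def build_training_set(
    chem: ChemistryModel, tg: TrainingGrid, grid: np.ndarray
) -> list[ExtinctionSpectrum]:
    """Sphere Q_ext training curves, one per (offset, radius), offset-major.

    All curves share the imaginary index k(nu) of ``chem``; each offset is
    substituted into the real part (the KK fluctuating part is unchanged,
    only the constant baseline moves).
    """
    grid = np.asarray(grid, dtype=float)
    k = synth_imag_index(chem, grid)
    n_fluct = kk_real_index(k, grid, n_offset=0.0)  # fluctuating part only
    curves: list[ExtinctionSpectrum] = []
    for offset in tg.offsets:
        m = RefractiveIndexSpectrum(grid=grid, n=n_fluct + offset, k=k)
        for radius in tg.radii:
            curves.append(qext_vdh_sphere(m, radius, grid))
    return curves


def fit_subspace(
    curves: list[ExtinctionSpectrum] | np.ndarray,
    max_comp: int,
    centered: bool = True,
) -> SubspaceBasis:
    """Compress training curves by PCA (SVD), keeping up to ``max_comp`` components.

    Components are orthonormal, ordered by explained variance, with a
    deterministic sign convention: the largest-magnitude element of each
    component is positive.  ``centered=False`` skips mean subtraction
    (the mean_curve is then zero and components span the raw curves).
    ``max_comp`` beyond the numerical rank is truncated with a warning.
    """
    if isinstance(curves, np.ndarray):
        X = np.asarray(curves, dtype=float)
        grid = np.arange(X.shape[1], dtype=float)
    else:
        if len(curves) < 2:
            raise ValueError("need at least 2 curves to fit a subspace")
        grid = curves[0].grid
        for c in curves[1:]:
            if c.grid.shape != grid.shape or not np.allclose(c.grid, grid):
                raise ValueError("training curves are on mismatched grids")
        X = np.stack([c.qext for c in curves])
    if max_comp > X.shape[0]:
        raise ValueError("max_comp cannot exceed the number of curves")

    mean = X.mean(axis=0) if centered else np.zeros(X.shape[1])
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)

    # absolute scale from the raw curves, so identical curves (zero after
    # centering, singular values at roundoff) register as rank 0
    scale = max(float(s[0]) if s.size else 0.0, float(np.linalg.norm(X)))
    tol = max(Xc.shape) * np.finfo(float).eps * scale
    rank = int(np.sum(s > tol))
    if max_comp > rank:
        warnings.warn(
            f"requested {max_comp} components but training matrix has rank {rank}; truncating",
            stacklevel=2,
        )
        max_comp = rank

    comps = Vt[:max_comp]
    # deterministic sign: largest-|.| element of each component positive
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    ev = s[:max_comp] ** 2 / max(X.shape[0] - (1 if centered else 0), 1)
    return SubspaceBasis(
        grid=grid, mean_curve=mean, components=comps, explained_variance=ev, centered=centered
    )


def _scores(target: np.ndarray, basis: SubspaceBasis, n_comp: int) -> np.ndarray:
    return basis.components[:n_comp] @ (target - basis.mean_curve)


def reconstruct(
    target: ExtinctionSpectrum | np.ndarray,
    basis: SubspaceBasis,
    n_comp: int,
    windows: dict[str, tuple[float, float]] | None = None,
) -> ReconstructionReport:
    """Project a target Q_ext curve onto the first ``n_comp`` components.

    reconstruction = mean + sum_i <target - mean, p_i> p_i.  The report
    carries the relative root-mean-square error (l2 residual over l2
    target) and, if ``windows`` are given, the residual energy (sum of
    squared residuals) inside each named wavenumber window.
    """
    if isinstance(target, ExtinctionSpectrum):
        if target.grid.shape != basis.grid.shape or not np.allclose(target.grid, basis.grid):
            raise ValueError("target grid does not match basis grid")
        y = target.qext
    else:
        y = np.asarray(target, dtype=float)
        if y.shape != basis.mean_curve.shape:
            raise ValueError("target length does not match basis grid")
    if not 1 <= n_comp <= basis.n_components:
        raise ValueError(f"n_comp must be in [1, {basis.n_components}]")

    scores = _scores(y, basis, n_comp)
    recon = basis.mean_curve + basis.components[:n_comp].T @ scores
    residual = y - recon
    denom = float(np.linalg.norm(y))
    rel_rmse = float(np.linalg.norm(residual) / denom) if denom > 0 else 0.0

    band_res: dict[str, float] = {}
    if windows:
        for name, (lo, hi) in windows.items():
            sel = (basis.grid >= lo) & (basis.grid <= hi)
            band_res[name] = float(np.sum(residual[sel] ** 2))
    return ReconstructionReport(
        n_comp=n_comp,
        reconstructed=recon,
        residual=residual,
        rel_rmse=rel_rmse,
        band_residuals=band_res,
    )


def sweep_ncomp(
    target: ExtinctionSpectrum | np.ndarray,
    basis: SubspaceBasis,
    n_comp_list: list[int],
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[ReconstructionReport]:
    """One reconstruction report per requested number of components."""
    return [reconstruct(target, basis, n, windows) for n in n_comp_list]


def band_windows(chem: ChemistryModel, half_width_fwhm: float = 2.0) -> dict[str, tuple[float, float]]:
    """Wavenumber windows center +/- ``half_width_fwhm`` x FWHM per band."""
    return {
        f"{band.center:g}": (
            band.center - half_width_fwhm * band.width,
            band.center + half_width_fwhm * band.width,
        )
        for band in chem.bands
    }


def peak_shift_experiment(
    chem: ChemistryModel,
    mapping: dict[float, float],
    basis: SubspaceBasis,
    geometry: ScattererGeometry,
    n_comp: int,
) -> tuple[ReconstructionReport, ReconstructionReport]:
    """Negative control: reconstruct targets from original vs shifted chemistry.

    The basis must be trained on the ORIGINAL chemistry.  Both the original
    and the band-shifted semi-capsule targets are projected onto it; the
    reports carry residual energies inside windows of +/- 2 FWHM around
    each *shifted* band center, so the two runs are compared in matched
    windows.  A chemistry-specific subspace reconstructs the original well
    but fails at the displaced bands.
    """
    grid = basis.grid
    shifted_chem = refindex.shift_bands(chem, mapping)
    windows = band_windows(shifted_chem)

    m_orig = refindex.synthesize(chem, grid)
    m_shift = refindex.synthesize(shifted_chem, grid)
    q_orig = qext_semicapsule(m_orig, geometry.R, geometry.L, grid)
    q_shift = qext_semicapsule(m_shift, geometry.R, geometry.L, grid)

    rep_orig = reconstruct(q_orig, basis, n_comp, windows)
    rep_shift = reconstruct(q_shift, basis, n_comp, windows)
    return rep_orig, rep_shift
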