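# Methods

## Physical model

All extinction models live in the anomalous-diffraction approximation
(ADA): the scatterer is large compared with the wavelength and optically
soft (|m − 1| not too large), so an incident ray is taken to traverse it
in a straight line, acquiring only the phase (and, for absorbing media,
attenuation) of the local chord. Interference of the phase-shifted
field with the unscattered field gives the extinction efficiency

    Q_ext(ν) = (2/A) ∬_A Re{1 − exp(i·k₀·(m(ν)−1)·t(x,y))} dA,

with k₀ = 2πν, projected area A and chord profile t. We use the
e^{−iωt} time convention, so absorbing media have Im m = k ≥ 0 and the
transmitted-ray factor decays. Wavenumbers are in cm⁻¹ and lengths in
µm (converted internally by 1e−4 cm/µm); the size parameter is
x = 2πνR and the complex phase parameter ρ = 2x(m−1).

Closed forms follow by evaluating the integral per geometry:

- **Sphere** (chord 2√(R²−r²) over a disk):
  Q = 4·Re{1/2 + e^(−a)/a − (1−e^(−a))/a²}, a = −iρ. For k = 0 this is
  the familiar 2 − (4/ρ)sin ρ + (4/ρ²)(1−cos ρ); for |a| < 1e−4 a series
  expansion avoids cancellation.
- **Dome**, illuminated along its axis (chord √(R²−r²)): the same
  kernel at a/2 — a dome is optically a sphere with half the path.
  Equivalently, Q_dome(R) = Q_sphere(R/2) at the same index.
- **Semi-cylinder**, normal incidence on the flat face, per unit
  length: the transverse chord integral reduces to
  Q = Re{π·H₁(c) − iπ·J₁(c)}, c = x(m−1), with the Struve function H₁
  and Bessel J₁ of complex argument (evaluated with mpmath;
  scipy.special.struve is restricted to real arguments).
- **Semi-capsule** (two quarter-sphere end caps + half-cylinder
  mid-section of length L): the projection is a stadium — a disk (the
  assembled dome) plus a 2R×L rectangle — and since the ADA integral is
  additive over disjoint projection regions,
  Q = (πR²·Q_dome + 2RL·Q_semicyl)/(πR² + 2RL). L = 0 degenerates to
  the dome exactly.

A numerical ADA oracle integrates the same integrand by adaptive
quadrature (scipy.integrate.quad, absolute tolerance 1e−10 on the
area-mean), exploiting each projection's symmetry: radial 1-D integrals
for disks, transverse 1-D integrals for strips, and their area-weighted
union for the stadium. A fully 2-D adaptive `dblquad` variant exists
for spot checks. The oracle is the arbiter of correctness for every
closed form (agreement ≤ 1e−6 relative in the tests; in practice
~1e−15).

The exact **Mie series** for the homogeneous sphere is the full-wave
reference: truncation at the Wiscombe order x + 4x^(1/3) + 2, the
logarithmic derivative Dₙ(mx) by downward recurrence started 15 orders
above the truncation, Riccati-Bessel functions ψₙ, χₙ by upward
recurrence (stable for the retained orders). The implementation is
cross-checked against the small-particle (Rayleigh) closed form and an
independent route built directly on scipy's spherical Bessel functions.

**Apparent absorbance.** With sample and aperture cross-sections g ≪ G,
Z = −log₁₀(1 − (g/G)·Q_ext), with the linearized form
(1/ln 10)(g/G)Q_ext available behind a flag. (g/G)·Q_ext ≥ 1 is
rejected: the aperture model cannot represent total extinction.

## Synthetic chemistry

The generator emulates the absorbing model material of the subspace
experiment: four Lorentz bands at 1500, 2010, 3000 and 5400 cm⁻¹ on a
constant real-index offset of 1.5. Band widths and peak heights are
not dictated by that experiment's description, so the defaults are
FWHM = 60 cm⁻¹ and peak imaginary index 0.1 — magnitudes typical of
strong mid-IR bands of organic materials and small against the 1.5
offset; both are configurable per band. The default wavenumber grid is
1000–6000 cm⁻¹ at 2 cm⁻¹ spacing, covering all four bands with margin.

The imaginary index is a sum of amplitude-normalized Lorentzians
a·(w/2)²/((ν−c)² + (w/2)²), so k(center) = a exactly. The real part
follows from the Kramers-Kronig (Hilbert-transform) dispersion
relation, evaluated with the Maclaurin alternating-point rule: the
principal-value sum at grid point i runs over points of opposite
parity, which steps over the singularity without special treatment; on
a uniform grid the sum is a convolution and is evaluated by FFT. The
grid is extended by 20% zero guard bands on each side to curb
truncation error. The sign convention (n above the offset on the
low-wavenumber side of an isolated band — anomalous dispersion) and the
accuracy are fixed by the analytic oracle: the one-pole complex
Lorentzian a·(w/2)/(c − ν − i·w/2), whose imaginary part equals the
generator's profile identically and whose real part is its exact
Hilbert transform. For the default bands the numerical transform
agrees with the oracle to ~0.1% of the dispersion amplitude over the
interior 80% of the grid. The discretization error of the Maclaurin
rule decays faster than quadratically once a band is resolved by a few
points per FWHM; the residual floor is set by the truncated Lorentzian
tails beyond the grid, ~1e−4 relative for the defaults.

This generator emulates the *optical* properties of an idealized
homogeneous material. It does not emulate instrument noise, baselines,
detector nonlinearity, water-vapor lines, non-Lorentzian (Gaussian or
Voigt) band shapes, or the inhomogeneous interior of a real cell —
passing tests therefore demonstrate correctness of the scattering and
subspace machinery under clean conditions, not robustness of ME-EMSC
preprocessing on measured spectra.

## The subspace experiment

The ME-EMSC meta-model represents scattering with a PCA-compressed set
of sphere extinction curves. The experiment reproduced here: 100 van de
Hulst sphere curves on a deterministic 10×10 grid — real-index offsets
1.3–1.7 × radii 5–10 µm (offset-major ordering), all sharing the
chemistry's k(ν) and its KK fluctuating real part — are mean-centered
and decomposed by SVD. Components carry a deterministic sign (largest-
magnitude element positive), making all downstream reports
bit-reproducible. The semi-capsule target (R = 10 µm, L = 10 µm, same
chemistry) is projected onto the leading n_comp components;
rel_rmse = ‖residual‖₂/‖target‖₂ is reported per n_comp together with
residual energies in band windows (center ± 2 FWHM).

Design choices made where the procedure was genuinely open:

- *Sampling of the training grid*: a regular 10×10 grid rather than
  random sampling — deterministic, matches the curve count, and a
  randomized-sampling robustness test shows the reconstruction error is
  insensitive to the scheme at this density.
- *PCA centering*: mean-centered by default; an uncentered variant is a
  flag, and the qualitative conclusions (monotone improvement with
  n_comp, chemistry specificity) hold under both.
- *rel_rmse*: ℓ₂ over the full grid; band windows ± 2 FWHM.

Measured behaviour (all recomputed by `scripts/acceptance.py`): the
reconstruction error falls monotonically with n_comp, from 5.4%
(n_comp = 5) to 1.3% (n_comp = 12) for L = 10 µm; longer elongations
need more components but remain reconstructable (L = 15 µm improves
threefold from 5 to 10 components). Twelve components do not exhaust
the training family itself — a sphere curve at an offset between
training offsets still leaves ~0.4% residual — so the few-percent
floor at moderate n_comp reflects the finite resolution of the
meta-model's parameter sampling as much as the out-of-family
semi-cylinder component of the capsule curve.

The peak-shift negative control moves the target's bands
(1500→1520, 2010→1950, 3000→3500, 5400→5350 cm⁻¹) while the basis
stays trained on the original chemistry: residual energy in the
shifted-band windows grows ~13× in aggregate, and the residual
concentrates inside those windows (~4.5× the outside density). Because
the projection is global, the outside-window residual also rises; the
localization, not baseline invariance, is the meaningful signature.

## Wiggle diagnostics

Wiggle positions are located with a prominence-filtered peak search
(10% of the curve's range) plus parabolic refinement. Exact Mie curves
carry ripples — sharp shape resonances the ADA cannot represent — so
they are suppressed before peak-picking by Savitzky-Golay smoothing
over a 240 cm⁻¹ window: about twice the ripple spacing for R = 10 µm,
n = 1.5, and a quarter of the wiggle period. On the 1000–6000 cm⁻¹
analysis window the first wiggle maxima of the exact Mie and van de
Hulst sphere curves then agree to 0.9%. The fundamental wiggle
(ρ ≈ 4.1, near 650 cm⁻¹ for this geometry) lies below the analysis
window; there the van de Hulst approximation places the maximum ~6%
below the exact Mie position — an intrinsic accuracy limit of the ADA
at m = 1.5, visible in both our series and the independent
spherical-Bessel cross-check, and the reason wiggle comparisons are
quoted on the analysis window where the approximation is used.

## Numerical choices and limitations

- Quadrature tolerances: 1e−10 (1-D oracles), 1e−8/1e−9 (2-D spot
  checks); non-convergence raises with the achieved estimate.
- The van de Hulst kernel switches to a 3-term series below |a| = 1e−4.
- Degenerate inputs: empty grids, non-uniform grids for the KK
  transform, L < 0, zero wavenumbers, and (g/G)Q ≥ 1 are rejected with
  specific errors; n < 1 is permitted but flagged.
- Polarization is absent from the ADA; the semi-cylinder result is
  per-length and polarization-averaged by construction. Ripples
  (whispering-gallery resonances) are outside the ADA's reach and are
  only represented by the exact Mie sphere reference.
- Substrate and coverslip effects are neglected throughout; scatterers
  are treated as isolated (coupling between neighbouring domes is not
  modelled).
- Problem sizes: the default experiment uses a 2501-point grid and 100
  training curves; oracle comparisons run on a 501-point grid — desk
  scale, seconds to minutes on one core.
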