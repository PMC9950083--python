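"""Extinction models: closed forms vs quadrature oracles, Mie, absorbance."""

import numpy as np
import pytest
from scipy import optimize

from domescatter.extinction import (
    ApertureGeometry,
    ScattererGeometry,
    absorbance_from_qext,
    ada_qext_radial,
    first_wiggle_maximum,
    qext_ada_numeric,
    qext_ada_area,
    qext_dome,
    qext_mie_exact,
    qext_semicapsule,
    qext_semicylinder,
    qext_vdh_sphere,
    rayleigh_qext,
)
from domescatter.refindex import default_grid


def rel_sup_err(a, b):
    return float(np.max(np.abs(a - b)) / np.max(np.abs(b)))


def nonabs_sphere_q(rho):
    """Non-absorbing van de Hulst closed form (independent reference)."""
    return 2.0 - 4.0 / rho * np.sin(rho) + 4.0 / rho**2 * (1.0 - np.cos(rho))


class TestVdhSphere:
    def test_vanishing_phase_limit(self):
        # rho -> 0+ via tiny radius
        q = qext_vdh_sphere(1.5, 1e-6, np.array([1000.0]))
        assert q.qext[0] == pytest.approx(0.0, abs=1e-8)

    def test_nonabsorbing_closed_form_and_first_wiggle(self):
        grid = default_grid(200, 1500, 1.0)
        q = qext_vdh_sphere(1.5, 10.0, grid)
        x = 2 * np.pi * grid * 10.0 * 1e-4
        rho = 2 * x * 0.5
        assert np.allclose(q.qext, nonabs_sphere_q(rho), atol=1e-12)
        # first wiggle max: root-find dQ/drho = 0 on the closed form
        def dq_drho(r):
            return -4 * np.cos(r) / r + 8 * np.sin(r) / r**2 - 8 * (1 - np.cos(r)) / r**3

        rho_star = optimize.brentq(dq_drho, 3.0, 6.0)
        nu_star = rho_star / (2 * np.pi * 10.0 * 1e-4)
        assert first_wiggle_maximum(grid, q.qext) == pytest.approx(nu_star, rel=1e-3)

    def test_matches_radial_quadrature_oracle_absorbing(self, index_spectrum, coarse_grid):
        from domescatter.refindex import default_chemistry, synthesize

        m = synthesize(default_chemistry(), coarse_grid)
        q = qext_vdh_sphere(m, 10.0, coarse_grid)
        qn = qext_ada_numeric(ScattererGeometry("sphere", 10.0), m, coarse_grid)
        assert rel_sup_err(q.qext, qn.qext) <= 1e-6

    def test_zero_wavenumber_rejected(self):
        with pytest.raises(ValueError):
            qext_vdh_sphere(1.5, 10.0, np.array([0.0, 100.0]))

    def test_n_below_one_flagged(self):
        with pytest.warns(UserWarning, match="n < 1"):
            qext_vdh_sphere(0.9, 10.0, np.array([1000.0]))


class TestDome:
    def test_equals_sphere_at_half_phase(self, index_spectrum, grid):
        # halving the phase parameter == halving the radius
        qd = qext_dome(index_spectrum, 10.0, grid)
        qs = qext_vdh_sphere(index_spectrum, 5.0, grid)
        assert np.max(np.abs(qd.qext - qs.qext)) <= 1e-12 * np.max(np.abs(qs.qext))

    def test_matches_quadrature_oracle(self, coarse_grid):
        q = qext_dome(1.5, 10.0, coarse_grid)
        qn = qext_ada_numeric(ScattererGeometry("dome", 10.0), 1.5, coarse_grid)
        assert rel_sup_err(q.qext, qn.qext) <= 1e-6


class TestSemiCylinder:
    def test_matches_strip_quadrature_oracle(self, coarse_grid):
        m = 1.5 + 0.05j
        q = qext_semicylinder(m, 10.0, coarse_grid)
        qn = qext_ada_numeric(ScattererGeometry("semi-cylinder", 10.0), m, coarse_grid)
        assert rel_sup_err(q.qext, qn.qext) <= 1e-6

    def test_extinction_paradox_at_large_phase(self):
        # rho = 200 -> c = 100: Q near 2 with decaying oscillation
        R = 10.0
        nu = 100.0 / (2 * np.pi * R * 1e-4 * 0.5)
        q = qext_semicylinder(1.5, R, np.array([nu]))
        assert q.qext[0] == pytest.approx(2.0, abs=0.15)

    def test_small_phase_limit(self):
        q = qext_semicylinder(1.5, 1e-5, np.array([1000.0]))
        assert q.qext[0] == pytest.approx(0.0, abs=1e-8)


class TestSemiCapsule:
    def test_zero_elongation_is_dome(self, index_spectrum, grid):
        qk = qext_semicapsule(index_spectrum, 10.0, 0.0, grid)
        qd = qext_dome(index_spectrum, 10.0, grid)
        assert np.max(np.abs(qk.qext - qd.qext)) <= 1e-12 * np.max(np.abs(qd.qext))

    def test_area_weighted_composition(self, index_spectrum, grid):
        R, L = 10.0, 7.5
        qd = qext_dome(index_spectrum, R, grid).qext
        qc = qext_semicylinder(index_spectrum, R, grid).qext
        expected = (np.pi * R**2 * qd + 2 * R * L * qc) / (np.pi * R**2 + 2 * R * L)
        qk = qext_semicapsule(index_spectrum, R, L, grid).qext
        assert np.max(np.abs(qk - expected)) <= 1e-10 * np.max(np.abs(expected))

    def test_matches_quadrature_oracle(self, coarse_grid):
        m = 1.5 + 0.03j
        q = qext_semicapsule(m, 10.0, 10.0, coarse_grid)
        qn = qext_ada_numeric(ScattererGeometry("semi-capsule", 10.0, 10.0), m, coarse_grid)
        assert rel_sup_err(q.qext, qn.qext) <= 1e-6

    def test_negative_elongation_rejected(self):
        with pytest.raises(ValueError):
            qext_semicapsule(1.5, 10.0, -1.0, np.array([1000.0]))

    def test_converges_to_semicylinder(self, coarse_grid):
        qc = qext_semicylinder(1.5, 10.0, coarse_grid).qext
        prev = np.inf
        for L in (0.0, 2.5, 5.0, 10.0, 15.0, 30.0, 150.0, 500.0):
            d = np.max(np.abs(qext_semicapsule(1.5, 10.0, L, coarse_grid).qext - qc))
            assert d <= prev + 1e-12
            prev = d
        assert d < 0.02 * np.max(qc)

    def test_wiggle_shifts_to_lower_wavenumber_with_elongation(self):
        g = default_grid(800, 3000, 2.0)
        positions = [
            first_wiggle_maximum(g, qext_semicapsule(1.5, 10.0, L, g).qext)
            for L in (0.0, 2.5, 5.0, 10.0, 15.0)
        ]
        assert all(a > b for a, b in zip(positions, positions[1:]))


class TestAdaOracles:
    def test_zero_chord_gives_zero(self):
        g = np.array([1000.0, 2000.0])
        q = ada_qext_radial(lambda r: 0.0 * r, 10.0, 1.5, g)
        assert np.allclose(q.qext, 0.0, atol=1e-12)

    def test_constant_chord_film_closed_form(self):
        # film of thickness t0: Q = 2 Re{1 - e^{i k0 (m-1) t0}}
        t0, m = 4.0, 1.5 + 0.02j
        g = np.array([1200.0, 3300.0])
        q = ada_qext_radial(lambda r: t0 + 0.0 * r, 10.0, m, g)
        k0 = 2 * np.pi * g
        expected = 2 * (1 - np.exp(1j * k0 * (m - 1) * t0 * 1e-4)).real
        assert np.max(np.abs(q.qext - expected)) <= 1e-9

    def test_2d_area_quadrature_agrees_on_stadium(self):
        # genuinely 2-D adaptive quadrature over the stadium projection,
        # spot-checked at a few wavenumbers against the closed form
        R, L, m = 10.0, 10.0, 1.5
        g = np.array([1100.0, 2500.0])

        def chord(x, y):
            if abs(x) <= L / 2:
                r2 = R**2 - y**2
            else:
                r2 = R**2 - (abs(x) - L / 2) ** 2 - y**2
            return np.sqrt(r2) if r2 > 0 else 0.0

        area = np.pi * R**2 + 2 * R * L
        qn = qext_ada_area(chord, (-L / 2 - R, L / 2 + R), (-R, R), area, m, g, tol=1e-8)
        qk = qext_semicapsule(m, R, L, g)
        assert rel_sup_err(qn.qext, qk.qext) < 1e-5


class TestMie:
    def test_rayleigh_limit(self):
        R = 10.0
        for x in (0.002, 0.01):
            nu = x / (2 * np.pi * R * 1e-4)
            q = qext_mie_exact(1.5, R, np.array([nu])).qext[0]
            expected = rayleigh_qext(1.5, np.array([x]))[0]
            assert q == pytest.approx(expected, rel=1e-3)

    def test_no_contrast_limit(self):
        q = qext_mie_exact(1.0 + 0j, 10.0, np.array([2000.0]))
        assert q.qext[0] == pytest.approx(0.0, abs=1e-10)

    def test_against_independent_bessel_route(self):
        # independent oracle: a_n, b_n from scipy spherical Bessel functions
        # directly, no logarithmic-derivative recurrence
        from scipy.special import spherical_jn, spherical_yn

        def mie_direct(m, x):
            nmax = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
            n = np.arange(1, nmax + 1)
            psi = x * spherical_jn(n, x)
            psim1 = x * spherical_jn(n - 1, x)
            chi = -x * spherical_yn(n, x)
            chim1 = -x * spherical_yn(n - 1, x)
            xi, xim1 = psi - 1j * chi, psim1 - 1j * chim1
            psip = psim1 - n / x * psi
            xip = xim1 - n / x * xi
            mx = m * x
            psimx = mx * spherical_jn(n, mx)
            psimxp = mx * spherical_jn(n - 1, mx) - n * spherical_jn(n, mx)
            a = (m * psimx * psip - psi * psimxp) / (m * psimx * xip - xi * psimxp)
            b = (psimx * psip - m * psi * psimxp) / (psimx * xip - m * xi * psimxp)
            return 2 / x**2 * np.sum((2 * n + 1) * (a + b).real)

        R = 10.0
        for x in (1.0, 5.0, 15.0, 30.0):
            nu = x / (2 * np.pi * R * 1e-4)
            mine = qext_mie_exact(1.5, R, np.array([nu])).qext[0]
            assert mine == pytest.approx(mie_direct(1.5, x), rel=1e-7)

    def test_complex_index_supported(self):
        q = qext_mie_exact(1.5 + 0.1j, 10.0, np.array([1000.0, 3000.0]))
        assert np.all(q.qext > 0) and np.all(np.isfinite(q.qext))

    def test_wiggles_align_with_vdh_inside_measurement_window(self):
        grid = default_grid(1000, 6000, 2.0)
        qm = qext_mie_exact(1.5, 10.0, grid).qext
        qv = qext_vdh_sphere(1.5, 10.0, grid).qext
        wm = first_wiggle_maximum(grid, qm, smooth_window=240.0)
        wv = first_wiggle_maximum(grid, qv)
        assert abs(wm - wv) / wv < 0.05


class TestAbsorbance:
    def test_zero_qext_gives_zero(self, grid):
        q = qext_vdh_sphere(1.0 + 0j, 10.0, grid[:5])
        z = absorbance_from_qext(q, ApertureGeometry(1.0, 100.0))
        assert np.allclose(z.z, 0.0, atol=1e-12)

    def test_exact_vs_linearized_forms(self):
        from domescatter.extinction import ExtinctionSpectrum

        q = ExtinctionSpectrum(
            np.array([1000.0]), np.array([2.0]), ScattererGeometry("sphere", 10.0), "mie-exact"
        )
        ap = ApertureGeometry(1.0, 100.0)  # g/G = 0.01
        z_exact = absorbance_from_qext(q, ap)
        z_lin = absorbance_from_qext(q, ap, linearized=True)
        assert z_exact.z[0] == pytest.approx(-np.log10(0.98), rel=1e-12)
        assert z_lin.z[0] == pytest.approx(0.02 / np.log(10), rel=1e-12)
        assert abs(z_exact.z[0] - z_lin.z[0]) / z_exact.z[0] < 0.015
        assert z_exact.linearized is False and z_lin.linearized is True

    def test_monotone_in_qext(self):
        from domescatter.extinction import ExtinctionSpectrum

        q = ExtinctionSpectrum(
            np.arange(1.0, 5.0),
            np.array([0.5, 1.0, 2.0, 3.0]),
            ScattererGeometry("sphere", 10.0),
            "mie-exact",
        )
        z = absorbance_from_qext(q, ApertureGeometry(1.0, 50.0))
        assert np.all(np.diff(z.z) > 0)

    def test_total_extinction_rejected(self):
        from domescatter.extinction import ExtinctionSpectrum

        q = ExtinctionSpectrum(
            np.array([1000.0]), np.array([3.0]), ScattererGeometry("sphere", 10.0), "mie-exact"
        )
        with pytest.raises(ValueError, match="aperture"):
            absorbance_from_qext(q, ApertureGeometry(40.0, 100.0))


class TestGeometryValidation:
    def test_elongation_only_for_semicapsule(self):
        with pytest.raises(ValueError):
            ScattererGeometry("dome", 10.0, 5.0)

    def test_semicapsule_l_zero_permitted(self):
        g = ScattererGeometry("semi-capsule", 10.0, 0.0)
        assert g.L == 0.0
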