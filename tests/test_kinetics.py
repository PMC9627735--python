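"""Forward-model tests: coefficients, closed form vs ODE, nucleation flux."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fibrilkit import (
    KineticParameters,
    derived_coefficients,
    fibril_mass_closed_form,
    integrate_moment_odes,
    nucleation_rate,
    oligomer_fold_change,
    total_nucleation_units,
)
from conftest import secondary_dominated_grid


def reaction_grid(params, span=30.0, n=400):
    c = derived_coefficients(params)
    return np.linspace(0.0, span / max(c.kappa, c.lam), n)


class TestDerivedCoefficients:
    def test_direct_substitution(self, ab42_params):
        """lambda and kappa equal direct evaluation of their definitions."""
        c = derived_coefficients(ab42_params)
        p = ab42_params
        lam = math.sqrt(2 * p.k_plus * p.k_n * p.m0**2)
        kap = math.sqrt(2 * p.k_plus * p.k_2 * p.m0**3)
        assert c.lam == pytest.approx(lam, rel=1e-14)
        assert c.kappa == pytest.approx(kap, rel=1e-14)
        # frozen regression values for this canonical parameter set
        assert c.lam == pytest.approx(1.2727922061357857e-04, rel=1e-12)
        assert c.kappa == pytest.approx(1.2727922061357855e-03, rel=1e-12)

    def test_no_primary_nucleation_degenerates(self):
        p = KineticParameters(k_n=0.0, k_plus=3e6, k_2=1e4, m0=3e-6)
        c = derived_coefficients(p)
        assert c.lam == 0.0
        assert c.C_plus == 0.0 and c.C_minus == 0.0
        assert c.k_inf_tilde == pytest.approx(c.k_inf, rel=1e-14)

    def test_requires_secondary_pathway(self, ab42_params):
        from dataclasses import replace

        with pytest.raises(ValueError):
            derived_coefficients(replace(ab42_params, k_2=0.0))
        with pytest.raises(ValueError):
            derived_coefficients(replace(ab42_params, k_plus=0.0))

    @given(
        k_n=st.floats(1e-7, 1e-1),
        k_plus=st.floats(1e4, 1e9),
        k_2=st.floats(1e2, 1e8),
    )
    @settings(max_examples=100, deadline=None)
    def test_identities_hold(self, k_n, k_plus, k_2):
        """C+ = -C-, B+B- = C+C-, and k_inf <= k_inf_tilde (since C+C- < 0)."""
        c = derived_coefficients(KineticParameters(k_n=k_n, k_plus=k_plus, k_2=k_2, m0=3e-6))
        assert c.C_plus == -c.C_minus
        assert c.B_plus * c.B_minus == pytest.approx(c.C_plus * c.C_minus, rel=1e-12, abs=1e-300)
        assert c.k_inf <= c.k_inf_tilde
        # exact relation between the two asymptotic rates
        assert c.k_inf_tilde**2 == pytest.approx(
            c.k_inf**2 - 4 * c.C_plus * c.C_minus * c.kappa**2, rel=1e-12
        )


class TestClosedForm:
    def test_boundary_values(self, ab42_params):
        t = reaction_grid(ab42_params)
        y = fibril_mass_closed_form(ab42_params, t)
        assert y[0] == 0.0
        assert y[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0) & (y <= 1))

    def test_rejects_seeded(self, ab42_params):
        from dataclasses import replace

        seeded = replace(ab42_params, M0=0.6e-6)
        with pytest.raises(ValueError):
            fibril_mass_closed_form(seeded, np.linspace(0, 10, 5))

    def test_half_time_matches_ode(self, ab42_params):
        t = reaction_grid(ab42_params)
        y_cf = fibril_mass_closed_form(ab42_params, t)
        traj = integrate_moment_odes(ab42_params, t)
        th_cf = np.interp(0.5, y_cf, t)
        assert th_cf == pytest.approx(traj.half_time(), rel=0.05)


class TestMomentOdes:
    def test_pure_elongation_linear_growth(self):
        """With k_n = k_2 = 0 the early seeded growth is 2 k+ m0 P0 t."""
        p = KineticParameters(
            k_n=0.0, k_plus=3e6, k_2=0.0, m0=3e-6, M0=0.6e-6, L_seed=2e4
        )
        t = np.linspace(0, 60.0, 50)  # 1 min: well inside the linear regime
        traj = integrate_moment_odes(p, t)
        expected = 2 * p.k_plus * p.m0 * (p.M0 / p.L_seed) * t
        assert traj.M - p.M0 == pytest.approx(expected, rel=1e-2)

    def test_no_growth_without_elongation(self):
        p = KineticParameters(k_n=3e-4, k_plus=0.0, k_2=1e4, m0=3e-6, M0=1e-7)
        traj = integrate_moment_odes(p, np.linspace(0, 1e5, 50))
        assert traj.M == pytest.approx(np.full_like(traj.t, p.M0), abs=1e-15)

    def test_mass_conservation_and_monotonicity(self, ab42_params):
        t = reaction_grid(ab42_params)
        traj = integrate_moment_odes(ab42_params, t)
        assert traj.m + traj.M == pytest.approx(
            np.full_like(t, ab42_params.m_total), rel=1e-9
        )
        assert np.all(np.diff(traj.M) >= -1e-18)

    def test_seeded_initial_fibril_number(self):
        p = KineticParameters(k_n=3e-5, k_plus=3e6, k_2=2e3, m0=3e-6, M0=0.6e-6, L_seed=100)
        traj = integrate_moment_odes(p, np.linspace(0, 10, 5))
        assert traj.P[0] == pytest.approx(p.M0 / p.L_seed)

    def test_oosawa_limit(self):
        """Negligible secondary nucleation reproduces the exact primary-only
        solution M/M_inf = 1 - sech^(2/nc)(sqrt(nc/2) lambda t)."""
        p = KineticParameters(k_n=3e-2, k_plus=3e6, k_2=1e-3, m0=3e-6)
        lam = derived_coefficients(p).lam
        t = np.linspace(0, 8 / lam, 200)
        y = integrate_moment_odes(p, t).normalized_mass
        y_exact = 1 - np.cosh(np.sqrt(p.n_c / 2) * lam * t) ** (-2 / p.n_c)
        assert y == pytest.approx(y_exact, abs=1e-5)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k_n=-1e-4, k_plus=3e6, k_2=1e4, m0=3e-6),
            dict(k_n=3e-4, k_plus=3e6, k_2=1e4, m0=3e-6, n_c=0.5),
            dict(k_n=3e-4, k_plus=3e6, k_2=1e4, m0=0.0),
            dict(k_n=3e-4, k_plus=3e6, k_2=1e4, m0=3e-6, M0=1e-7, L_seed=1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParameters(**kwargs)


class TestNucleationFlux:
    def test_pointwise_formula(self, ab42_params):
        t = reaction_grid(ab42_params)
        traj = integrate_moment_odes(ab42_params, t)
        r = nucleation_rate(ab42_params, traj)
        p = ab42_params
        # unseeded start: only the primary term
        assert r[0] == pytest.approx(p.k_n * p.m0**p.n_c, rel=1e-12)
        mid = len(t) // 2
        expect = p.k_n * traj.m[mid] ** p.n_c + p.k_2 * traj.M[mid] * traj.m[mid] ** p.n_2
        assert r[mid] == pytest.approx(expect, rel=1e-12)
        # exhausted monomer -> vanishing flux
        assert r[-1] <= 1e-3 * r.max()
        assert np.all(r >= 0)

    def test_total_units_quadrature_oracle_primary_only(self):
        """With k_2 = 0 the total equals an independent quadrature of
        k_n m(t)^nc over an independently integrated trajectory."""
        p = KineticParameters(k_n=3e-4, k_plus=3e6, k_2=0.0, m0=3e-6)

        def rhs(t, y):
            P, M = y
            m = max(p.m0 - M, 0.0)
            return [p.k_n * m**2, 2 * p.k_plus * m * P]

        t_end = 3e5
        sol = solve_ivp(rhs, (0, t_end), [0.0, 0.0], rtol=1e-10, atol=1e-20, dense_output=True)
        tt = np.linspace(0, t_end, 40001)
        m = np.clip(p.m0 - sol.sol(tt)[1], 0, None)
        oracle = np.trapezoid(p.k_n * m**2, tt)
        assert sol.sol(t_end)[1] / p.m0 > 0.999
        assert total_nucleation_units(p, horizon=t_end) == pytest.approx(oracle, rel=5e-3)

    def test_total_units_monotone_in_k_n(self):
        p = KineticParameters(k_n=3e-4, k_plus=3e6, k_2=0.0, m0=3e-6)
        assert total_nucleation_units(p.scaled(k_n=2.0)) > total_nucleation_units(p)

    def test_blocking_elongation_increases_units(self, ab42_params):
        base = total_nucleation_units(ab42_params)
        blocked = total_nucleation_units(ab42_params.scaled(k_plus=0.1))
        assert blocked > base

    def test_suppressing_secondary_decreases_units(self, ab42_params):
        base = total_nucleation_units(ab42_params)
        suppressed = total_nucleation_units(ab42_params.scaled(k_2=0.5))
        assert suppressed < base


class TestOligomerFoldChange:
    def test_identity(self, ab42_params):
        assert oligomer_fold_change(ab42_params, ab42_params) == 1.0

    def test_end_blocking_regression_value(self, ab42_params):
        """k+ x0.05, k2 x0.5: more oligomers; value frozen from the
        quadrature oracle at first computation."""
        inhibited = ab42_params.scaled(k_plus=0.05, k_2=0.5)
        fold = oligomer_fold_change(ab42_params, inhibited)
        assert fold > 1.0
        assert fold == pytest.approx(3.186, rel=0.02)

    def test_requires_shared_conditions(self, ab42_params):
        other = KineticParameters(k_n=3e-4, k_plus=3e6, k_2=1e4, m0=5e-6)
        with pytest.raises(ValueError):
            oligomer_fold_change(ab42_params, other)


class TestHalfTimeMonotonicity:
    @pytest.mark.parametrize("constant", ["k_n", "k_plus", "k_2"])
    def test_half_time_decreases_when_rate_increases(self, constant):
        for p in secondary_dominated_grid(6, seed=3):
            t = reaction_grid(p)
            faster = p.scaled(**{constant: 3.0})
            th_base = np.interp(0.5, fibril_mass_closed_form(p, t), t)
            th_fast = np.interp(0.5, fibril_mass_closed_form(faster, t), t)
            assert th_fast < th_base
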