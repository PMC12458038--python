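"""Kinetic ODEs, their closed-form/RK4 oracles, and the model fits."""

import math

import numpy as np
import pandas as pd
import pytest

import fccs_kin as fk
from fccs_kin.kinetics import DepletionIsothermModel, equilibrium_complex


# ---------------------------------------------------------------------------
# independent oracles (used only by tests)
# ---------------------------------------------------------------------------

def riccati_closed_form(P0, L0, k_on, k_off, t):
    """Closed-form solution of dC/dt = k_on (P0-C)(L0-C) - k_off C, C(0)=0.

    The quadratic k_on C^2 - b C + k_on P0 L0 (b = k_on (P0+L0) + k_off) has
    roots r- < r+; the trajectory is
    C(t) = r+ r- (1 - exp(-k_on (r+ - r-) t)) / (r+ - r- exp(-k_on (r+-r-) t)).
    """
    b = k_on * (P0 + L0) + k_off
    disc = math.sqrt(b * b - 4 * k_on * k_on * P0 * L0)
    r_plus = (b + disc) / (2 * k_on)
    r_minus = (b - disc) / (2 * k_on)
    e = np.exp(-k_on * (r_plus - r_minus) * np.asarray(t, dtype=float))
    return r_plus * r_minus * (1 - e) / (r_plus - r_minus * e)


def rk4(rhs, y0, times):
    """Fixed-step 4th-order Runge-Kutta reference integrator."""
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for t0, t1 in zip(times[:-1], times[1:]):
        n_sub = 200
        h = (t1 - t0) / n_sub
        for i in range(n_sub):
            t = t0 + i * h
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


# Fig-2-style reference condition (nonconfined DNA ligand)
P0, L0 = 1.3e-9, 6.4e-9
K_ON, K_OFF = 2.7e5, 3.9e-4


class TestBoundFractionODE:
    def test_matches_closed_form_trajectory(self):
        times = np.linspace(0.0, 3600.0, 25)
        c = fk.bound_fraction_ode(P0, L0, K_ON, K_OFF, times)
        np.testing.assert_allclose(c, riccati_closed_form(P0, L0, K_ON, K_OFF, times),
                                   rtol=1e-6, atol=1e-18)

    def test_twenty_minute_value_and_equilibrium_root(self):
        c_1200 = fk.bound_fraction_ode(P0, L0, K_ON, K_OFF, np.array([0.0, 1200.0]))[-1]
        assert c_1200 == pytest.approx(riccati_closed_form(P0, L0, K_ON, K_OFF, 1200.0),
                                       rel=1e-6)
        # long-time limit equals the smaller quadratic root
        c_eq = fk.bound_fraction_ode(P0, L0, K_ON, K_OFF, np.array([0.0, 1e6]))[-1]
        assert c_eq == pytest.approx(equilibrium_complex(P0, L0, K_OFF / K_ON), rel=1e-6)

    def test_initial_condition_and_irreversible_limit(self):
        assert fk.bound_fraction_ode(P0, L0, K_ON, K_OFF, np.array([0.0]))[0] == 0.0
        c = fk.bound_fraction_ode(P0, 100 * P0, K_ON, 0.0, np.array([0.0, 1e6]))[-1]
        assert c == pytest.approx(P0, rel=1e-6)

    def test_monotone_nondecreasing(self):
        c = fk.bound_fraction_ode(P0, L0, K_ON, K_OFF, np.linspace(0, 7200, 200))
        assert np.all(np.diff(c) >= -1e-15)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fk.bound_fraction_ode(-P0, L0, K_ON, K_OFF, np.array([0.0, 1.0]))

    def test_pseudo_first_order_limit(self):
        """At L0 = 1000 P0 the exact ODE and the exponential model agree to 1%."""
        p0 = 1e-12
        l0 = 1000 * p0
        k_eq = K_ON * l0 + K_OFF
        times = np.linspace(0, 5 / k_eq, 60)
        c_full = fk.bound_fraction_ode(p0, l0, K_ON, K_OFF, times)
        c_eq_full = equilibrium_complex(p0, l0, K_OFF / K_ON)
        f_pseudo = 1.0 - np.exp(-k_eq * times)
        assert np.max(np.abs(c_full / c_eq_full - f_pseudo)) <= 0.01


class TestEquilibriumComplex:
    def test_tight_binding_limit_is_stoichiometric(self):
        assert equilibrium_complex(1.3e-9, 0.5e-9, 0.0) == pytest.approx(0.5e-9)
        assert equilibrium_complex(1.3e-9, 5e-9, 0.0) == pytest.approx(1.3e-9)

    def test_weak_binding_limit_is_hyperbolic(self):
        kd = 1e-6  # far above both totals
        c = equilibrium_complex(1e-9, 2e-9, kd)
        assert c == pytest.approx(1e-9 * 2e-9 / kd, rel=1e-3)


class TestPseudoFirstOrder:
    def test_identities(self):
        assert fk.pseudo_first_order_timecourse(60.0, 1e-3, 0.0) == 0.0
        assert fk.pseudo_first_order_timecourse(60.0, 1e-3, 1e9) == pytest.approx(60.0)
        half = fk.pseudo_first_order_timecourse(60.0, 1e-3, math.log(2) / 1e-3)
        assert half == pytest.approx(30.0, rel=1e-12)

    def test_fig2_style_curve_matches_arithmetic(self):
        """A = 60, k_eq = 2.7e5*6.4e-9 + 3.9e-4 s^-1 on a 0-180 min grid."""
        k_eq = K_ON * L0 + K_OFF
        assert k_eq == pytest.approx(2.118e-3, rel=1e-3)
        t = np.arange(0.0, 180.1, 5.0) * 60.0
        vals = fk.pseudo_first_order_timecourse(60.0, k_eq, t)
        expected = 60.0 * (1.0 - np.exp(-k_eq * t))
        np.testing.assert_allclose(vals, expected, rtol=1e-12)
        assert vals[-1] == pytest.approx(60.0, rel=1e-6)  # fully plateaued


class TestEquilibrationFit:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 7200, 30)
        df = pd.DataFrame({"t_s": t, "ccp": fk.pseudo_first_order_timecourse(60, 1e-3, t)})
        res = fk.fit_equilibration(df)
        assert res.converged
        assert res.A == pytest.approx(60.0, rel=1e-8)
        assert res.k_eq == pytest.approx(1e-3, rel=1e-8)

    def test_all_zero_data_flagged_unidentifiable(self):
        df = pd.DataFrame({"t_s": np.linspace(0, 100, 10), "ccp": np.zeros(10)})
        res = fk.fit_equilibration(df)
        assert not res.converged
        assert "k_eq_unidentifiable" in res.flags

    def test_ode_generated_pseudo_first_order_rate(self):
        """ODE data at L0 = 100 P0 invert to k_eq = k_on L0 + k_off within 2%."""
        p0 = 1.3e-11
        l0 = 100 * p0
        times = np.linspace(0, 4 / (K_ON * l0 + K_OFF), 40)
        c = fk.bound_fraction_ode(p0, l0, K_ON, K_OFF, times)
        df = pd.DataFrame({"t_s": times, "ccp": 60 * c / p0})
        res = fk.fit_equilibration(df)
        assert res.k_eq == pytest.approx(K_ON * l0 + K_OFF, rel=0.02)


class TestRateLaw:
    def test_exact_line_recovered(self):
        conc = np.array([0.7, 1.2, 1.4, 1.6, 1.9, 2.7, 6.4]) * 1e-9
        k_eq = K_ON * conc + K_OFF
        res = fk.fit_rate_law(pd.DataFrame({"L_conc_M": conc, "k_eq": k_eq}))
        assert res.k_on == pytest.approx(K_ON, rel=1e-10)
        assert res.k_off_intercept == pytest.approx(K_OFF, rel=1e-8)
        assert "unreliable_intercept" in res.flags
        assert res.rsquared == pytest.approx(1.0)

    def test_flat_rates_give_zero_slope(self):
        conc = np.array([1.0, 2.0, 3.0]) * 1e-9
        res = fk.fit_rate_law(pd.DataFrame({"L_conc_M": conc, "k_eq": [1e-3] * 3}))
        # numerically zero on the k_on scale (~1e5 M^-1 s^-1)
        assert res.k_on == pytest.approx(0.0, abs=1e-3)

    def test_underdetermined_input_rejected(self):
        with pytest.raises(ValueError):
            fk.fit_rate_law(pd.DataFrame({"L_conc_M": [1e-9, 2e-9], "k_eq": [1, 2]}))

    def _ode_chain_slope(self, conc_scale):
        conc = np.array([0.7, 1.2, 1.4, 1.6, 1.9, 2.7, 6.4]) * 1e-9 * conc_scale
        rows = []
        for l0 in conc:
            k_eq_true = K_ON * l0 + K_OFF
            t = np.linspace(0, 5 / k_eq_true, 40)
            c = fk.bound_fraction_ode(P0, l0, K_ON, K_OFF, t)
            fit = fk.fit_equilibration(pd.DataFrame({"t_s": t, "ccp": 60 * c / P0}))
            rows.append((l0, fit.k_eq))
        return fk.fit_rate_law(rows).k_on

    def test_full_ode_chain_recovers_k_on_in_excess_ligand(self):
        """Exact-ODE time courses invert to k_on within 3% once [L] >> P0."""
        assert self._ode_chain_slope(10.0) == pytest.approx(K_ON, rel=0.03)

    def test_full_ode_chain_biased_low_under_depletion(self):
        """At the printed near-stoichiometric concentrations the same chain
        underestimates k_on: ligand depletion breaks pseudo-first-order."""
        slope = self._ode_chain_slope(1.0)
        assert slope < 0.95 * K_ON
        assert slope == pytest.approx(K_ON, rel=0.25)


class TestIsotherms:
    def test_half_saturation_identity(self):
        conc = np.geomspace(0.2, 20, 12) * 1e-9
        df = pd.DataFrame({"L_conc_M": conc, "ccp": 60 * conc / (conc + 1.4e-9)})
        res = fk.fit_isotherm(df)
        assert res.A == pytest.approx(60.0, rel=1e-8)
        assert res.K_d == pytest.approx(1.4e-9, rel=1e-8)
        assert res.predict([res.K_d])[0] == pytest.approx(res.A / 2, rel=1e-8)

    def test_fitted_curve_monotone_and_bounded(self):
        conc = np.geomspace(0.2, 20, 10) * 1e-9
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "L_conc_M": conc,
            "ccp": 60 * conc / (conc + 1.4e-9) + rng.normal(0, 2, conc.size),
        })
        res = fk.fit_isotherm(df)
        grid = np.geomspace(1e-11, 1e-6, 100)
        pred = res.predict(grid)
        assert np.all(np.diff(pred) > 0)
        assert np.all(pred <= res.A + 1e-9)

    def test_depletion_data_bias_hyperbolic_fit_positive(self):
        """With P0 ~ [L], the plain hyperbolic K_d is biased high."""
        kd = 1.4e-9
        conc = np.array([0.7, 1.2, 1.4, 1.6, 1.9, 2.7, 6.4]) * 1e-9
        ccp = 60 * np.array([equilibrium_complex(P0, l, kd) for l in conc]) / P0
        df = pd.DataFrame({"L_conc_M": conc, "ccp": ccp})
        hyp = fk.fit_isotherm(df)
        dep = fk.fit_isotherm_depletion(df, P0=P0)
        assert dep.K_d == pytest.approx(kd, rel=1e-6)
        assert hyp.K_d > kd  # depletion masquerades as weaker binding

    def test_depletion_reduces_to_hyperbola_for_weak_binding(self):
        kd = 1e-6  # >> P0
        conc = np.geomspace(0.05, 20, 30) * 1e-6
        model = DepletionIsothermModel(conc, np.zeros_like(conc), P0=1.3e-9)
        dep_curve = model._func(conc, 60.0, kd)
        hyp_curve = 60.0 * conc / (conc + kd)
        assert np.max(np.abs(dep_curve - hyp_curve) / hyp_curve) < 0.01

    def test_depletion_stoichiometric_limit(self):
        conc = np.array([0.2, 0.6, 1.0, 1.3, 1.8, 3.0]) * 1e-9
        model = DepletionIsothermModel(conc, np.zeros_like(conc), P0=1.3e-9)
        vals = model._func(conc, 60.0, 0.0)
        expected = 60.0 * np.minimum(conc, 1.3e-9) / 1.3e-9
        np.testing.assert_allclose(vals, expected, rtol=1e-9)

    def test_depletion_self_recovery_in_picomolar_regime(self):
        conc = np.array([0.2, 0.4, 0.6, 0.9, 1.1, 1.2, 1.3, 1.4, 1.7, 2.3, 4.0]) * 1e-9
        ccp = 60 * np.array([equilibrium_complex(1.3e-9, l, 4e-12) for l in conc]) / 1.3e-9
        res = fk.fit_isotherm_depletion(
            pd.DataFrame({"L_conc_M": conc, "ccp": ccp}), P0=1.3e-9
        )
        assert res.A == pytest.approx(60.0, rel=1e-6)
        assert res.K_d == pytest.approx(4e-12, rel=1e-4)


class TestDisplacement:
    def test_no_competitor_means_no_decay(self):
        times = np.linspace(0, 600, 30)
        c = fk.displacement_ode(1.3e-9, 30e-9, 0.0, 1.7e5, 5.4e-3, times)
        assert np.ptp(c) / c[0] < 1e-6

    def test_irreversible_bond_never_displaced(self):
        times = np.linspace(0, 600, 30)
        c = fk.displacement_ode(1.3e-9, 30e-9, 1e-6, 1.7e5, 0.0, times)
        np.testing.assert_allclose(c, c[0], rtol=1e-9)

    def test_matches_rk4_reference_integrator(self):
        k_on, k_off = 1.7e5, 5.4e-3
        p0, ls, lu = 1.3e-9, 30e-9, 1000e-9
        times = np.linspace(0, 900, 10)
        c = fk.displacement_ode(p0, ls, lu, k_on, k_off, times)
        c0 = equilibrium_complex(p0, ls, k_off / k_on)

        def rhs(_t, y):
            cs, cu = y
            p_free = p0 - cs - cu
            return np.array([
                k_on * (ls - cs) * p_free - k_off * cs,
                k_on * (lu - cu) * p_free - k_off * cu,
            ])

        ref = rk4(rhs, [c0, 0.0], times)[:, 0]
        np.testing.assert_allclose(c, ref, rtol=1e-6)

    def test_large_excess_decay_rate_approaches_k_off(self):
        """Fitted displacement-decay rate within 10% of k_off under 1000 nM competitor."""
        k_on, k_off = 1.7e5, 5.4e-3
        times = np.arange(0.0, 901.0, 15.0)
        c = fk.displacement_ode(1.3e-9, 30e-9, 1000e-9, k_on, k_off, times)
        res = fk.fit_displacement(pd.DataFrame({"t_s": times, "ccp": 60 * c / 1.3e-9}))
        assert res.converged
        assert res.k_off == pytest.approx(k_off, rel=0.10)

    def test_noiseless_eq6_exact_recovery(self):
        t = np.linspace(0, 600, 40)
        ccp = 50.0 * np.exp(-1.1e-2 * t) + 5.0
        res = fk.fit_displacement(pd.DataFrame({"t_s": t, "ccp": ccp}))
        assert res.A_prime == pytest.approx(50.0, rel=1e-8)
        assert res.k_off == pytest.approx(1.1e-2, rel=1e-8)
        assert res.o == pytest.approx(5.0, rel=1e-6)

    def test_constant_decay_flagged(self):
        df = pd.DataFrame({"t_s": np.linspace(0, 600, 10), "ccp": np.full(10, 30.0)})
        with pytest.warns(UserWarning, match="decreasing"):
            res = fk.fit_displacement(df)
        assert not res.converged
        assert "k_off_unidentifiable" in res.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fk.fit_displacement(pd.DataFrame({"t_s": [0, 1, 2], "ccp": [3, 2, 1]}))


class TestAffinityClosure:
    def test_derive_k_off_from_measured_pair(self):
        rec = fk.complete_affinity(Kd=1.5e-9, Kd_err=0.4e-9, k_on=1.0e5, k_on_err=0.3e5)
        assert rec.k_off == pytest.approx(1.5e-4, rel=1e-12)
        assert rec.provenance["k_off"] == "derived-via-closure"
        expected_err = 1.5e-4 * math.sqrt((0.4 / 1.5) ** 2 + (0.3 / 1.0) ** 2)
        assert rec.k_off_err == pytest.approx(expected_err, rel=1e-12)

    def test_derive_k_on_from_measured_pair(self):
        rec = fk.complete_affinity(k_off=0.54e-2, k_off_err=0.06e-2,
                                   Kd=3.2e-8, Kd_err=1.1e-8)
        assert rec.k_on == pytest.approx(1.6875e5, rel=1e-12)
        assert round(rec.k_on / 1e5, 1) == 1.7  # two significant figures

    def test_identity_triple(self):
        rec = fk.complete_affinity(k_on=1.0, k_off=1.0)
        assert rec.Kd == pytest.approx(1.0)

    @pytest.mark.parametrize("kd,kon,koff", [(1.4e-9, 2.7e5, None),
                                             (None, 1.0e5, 1.5e-4),
                                             (3.2e-8, None, 0.54e-2)])
    def test_closure_is_exact_for_any_pair(self, kd, kon, koff):
        rec = fk.complete_affinity(Kd=kd, k_on=kon, k_off=koff)
        assert rec.closure_ratio() == pytest.approx(1.0, rel=1e-12)

    def test_wrong_input_count_rejected(self):
        with pytest.raises(ValueError, match="exactly two"):
            fk.complete_affinity(Kd=1e-9)
        with pytest.raises(ValueError, match="exactly two"):
            fk.complete_affinity(Kd=1e-9, k_on=1e5, k_off=1e-4)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fk.complete_affinity(Kd=0.0, k_off=1e-4)


class TestResultsInterface:
    def test_summary_contains_estimates_and_errors(self):
        t = np.linspace(0, 7200, 30)
        df = pd.DataFrame({"t_s": t, "ccp": fk.pseudo_first_order_timecourse(60, 1e-3, t)})
        res = fk.fit_equilibration(df)
        text = res.summary()
        assert "A" in text and "k_eq" in text and "converged = True" in text
        assert res.cov_params.shape == (2, 2)
        assert np.allclose(res.cov_params, res.cov_params.T)
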