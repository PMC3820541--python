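"""Relaxed-assumption model variants and their sigmoidality claims."""

import numpy as np
import pytest
from dataclasses import replace

from scipy.integrate import solve_ivp

from phosphorelay.core_model import ParameterSet, bind_parameters, ode_rhs, \
    topology_by_id
from phosphorelay.steady_state import maximal_response, ode_steady_state, \
    signal_for_response
from phosphorelay.variants import (
    VariantSpec,
    _bifunctional_alpha,
    bifunctional_signal_for_response,
    effective_parameters,
    variant_condition_checks,
    variant_conservation,
    variant_curvature_at_zero,
    variant_initial_state,
    variant_maximal_response,
    variant_rhs,
    variant_signal_for_response,
    variant_steady_curve,
    variant_steady_state,
)


@pytest.fixture(scope="module")
def bif_params(request):
    """Reference bifunctional-regime set (explicit k_5/k_5r/k_6)."""
    return ParameterSet(k_2=9343, k_3=30201, k_4=35826, k_2r=0, k_3r=7192,
                        k_4r=99251, k_h1=0.0302, k_h2=0.00234,
                        k_5=1000, k_5r=0.012, k_6=3.5,
                        HK_tot=1.2748e-04, REC_tot=1.5755e-04,
                        Hpt_tot=1.3634e-04, RR_tot=1.2516e-04)


def _integrate(rhs, y0, t_end=20.0):
    sol = solve_ivp(rhs, (0, t_end), y0, method="LSODA", rtol=1e-10,
                    atol=1e-14, dense_output=False)
    assert sol.success
    return sol


class TestReductions:
    """Every variant collapses onto the simple model at zero extra rates."""

    @pytest.mark.parametrize("variant", [
        VariantSpec("bifunctional_hk"),
        VariantSpec("turnover", delta=0.0),
        VariantSpec("hk_autodephos", k_hk=0.0),
        VariantSpec("hpt_autodephos", k_hpt=0.0),
    ])
    def test_trajectories_coincide(self, t30, tuning_params, variant):
        p = replace(bind_parameters(t30, tuning_params), k_s=1.0)
        y0v = variant_initial_state(p, variant)
        solv = _integrate(lambda t, y: variant_rhs(t, y, p, variant), y0v)
        sols = _integrate(lambda t, y: ode_rhs(t, y, p), y0v[:8])
        assert np.max(np.abs(solv.y[:8, -1] - sols.y[:, -1])) < 1e-9

    def test_effective_elimination_reduces(self, t30, tuning_params):
        v = VariantSpec("turnover", delta=0.0)
        a = variant_maximal_response(t30, tuning_params, v)
        assert a == pytest.approx(maximal_response(t30, tuning_params),
                                  rel=1e-9)


class TestEightSpeciesVariants:
    @pytest.mark.parametrize("variant", [
        VariantSpec("turnover", delta=0.05),
        VariantSpec("hk_autodephos", k_hk=0.3),
        VariantSpec("hpt_autodephos", k_hpt=0.3),
    ])
    def test_elimination_matches_ode(self, t30, tuning_params, variant):
        """The generalized flux-balance elimination reproduces the variant
        ODE steady state."""
        alpha = variant_maximal_response(t30, tuning_params, variant)
        rr = 0.4 * alpha
        ks = variant_signal_for_response(rr, t30, tuning_params, variant)
        y = variant_steady_state(t30, tuning_params, variant, ks,
                                 tol_factor=1e-11)
        assert y[7] == pytest.approx(rr, rel=1e-6)

    def test_turnover_totals_return_to_target(self, t30, tuning_params):
        """Production/removal keeps steady-state layer totals at X_tot."""
        v = VariantSpec("turnover", delta=0.2)
        y = variant_steady_state(t30, tuning_params, v, 1.0)
        totals = variant_conservation(y, tuning_params, v)
        assert totals == pytest.approx(np.array(tuning_params.totals),
                                       rel=1e-6)

    def test_effective_parameters_mapping(self, t30, tuning_params):
        p_eff, kh0, kh3 = effective_parameters(
            t30, tuning_params, VariantSpec("turnover", delta=0.1))
        assert p_eff.k_h1 == tuning_params.k_h1 + 0.1
        assert p_eff.k_h2 == tuning_params.k_h2 + 0.1
        assert kh0 == kh3 == 0.1


class TestBifunctional:
    def test_conservation_includes_complex(self, t30, bif_params):
        v = VariantSpec("bifunctional_hk")
        p = replace(bind_parameters(t30, bif_params), k_s=0.05)
        y0 = variant_initial_state(p, v)
        sol = _integrate(lambda t, y: variant_rhs(t, y, p, v), y0,
                         t_end=200.0)
        for y in sol.y.T[::10]:
            totals = variant_conservation(y, p, v)
            assert totals[0] == pytest.approx(p.HK_tot, rel=1e-8)
            assert totals[1] == pytest.approx(p.REC_tot, rel=1e-8)

    def test_reference_set_reaches_steady_state_with_complex(self, t30,
                                                              bif_params):
        v = VariantSpec("bifunctional_hk")
        y = variant_steady_state(t30, bif_params, v, 0.05)
        assert y[8] > 0.0  # HK-REC~P complex present at steady state
        assert np.all(y >= -1e-12)

    def test_alpha_unchanged(self, t30, bif_params):
        """HK bifunctionality does not move the maximal response."""
        assert _bifunctional_alpha(t30, bif_params) == pytest.approx(
            maximal_response(t30, bif_params), rel=1e-8)

    def test_half_maximal_signal_increases(self, t30, bif_params):
        """Sequestration/dephosphorylation by bifunctional HK demands more
        signal for the same response."""
        alpha = _bifunctional_alpha(t30, bif_params)
        for frac in (0.25, 0.5, 0.75):
            rr = frac * alpha
            ks_bif = bifunctional_signal_for_response(rr, t30, bif_params)
            ks_mono = signal_for_response(rr, t30, bif_params)
            assert ks_bif > ks_mono

    def test_semi_analytic_f_matches_ode(self, t30, bif_params):
        v = VariantSpec("bifunctional_hk")
        alpha = _bifunctional_alpha(t30, bif_params)
        rr = 0.5 * alpha
        ks = bifunctional_signal_for_response(rr, t30, bif_params)
        y = variant_steady_state(t30, bif_params, v, ks, tol_factor=1e-11)
        assert y[7] == pytest.approx(rr, rel=1e-6)


class TestComplexes:
    def test_conservation_with_complexes(self, t30, tuning_params):
        p = replace(bind_parameters(t30, tuning_params), k_s=1.0)
        v = VariantSpec.complexes_matching(t30, p, off=50.0, cat=50.0)
        y0 = variant_initial_state(p, v)
        sol = _integrate(lambda t, y: variant_rhs(t, y, p, v), y0)
        for y in sol.y.T[::10]:
            totals = variant_conservation(y, p, v)
            assert np.allclose(totals, p.totals, rtol=1e-8)

    def test_fast_complex_limit_recovers_simple_model(self, t30,
                                                      tuning_params):
        """With short-lived encounter complexes and matched net rates the
        steady-state response approaches the simple model's."""
        p = bind_parameters(t30, tuning_params)
        ks = 1.0
        rr_simple = ode_steady_state(t30, p, ks)[7]
        v = VariantSpec.complexes_matching(t30, p, off=2000.0, cat=2000.0)
        y = variant_steady_state(t30, p, v, ks)
        assert y[7] == pytest.approx(rr_simple, rel=1e-2)


class TestConditionClaims:
    def test_hpt_autodephos_witness(self):
        """Hpt auto-dephosphorylation admits sigmoidality with k_h1 = k_3r
        = 0 provided k_4r > k_4."""
        rep = variant_condition_checks("hpt_autodephos", seed=2,
                                       n_draws=2000)
        assert rep.passed
        p, v = rep.witnesses[0]
        assert p.k_h1 == 0.0 and p.k_3r == 0.0 and p.k_4r > p.k_4
        top = topology_by_id(3)
        assert variant_curvature_at_zero(top, p, v) > 0

    def test_turnover_witness(self):
        """Turnover admits sigmoidality with k_h1 = k_3r = 0 and k_4r > 0."""
        rep = variant_condition_checks("turnover", seed=2, n_draws=2000)
        assert rep.passed
        p, v = rep.witnesses[0]
        assert p.k_h1 == 0.0 and p.k_3r == 0.0 and p.k_4r > 0.0

    def test_hk_autodephos_preserves_necessary_conditions(self):
        """HK auto-dephosphorylation leaves the simple model's necessary
        conditions intact: no sigmoidal draw violates them."""
        rep = variant_condition_checks("hk_autodephos", seed=2,
                                       n_draws=1500)
        assert rep.passed and not rep.counterexamples

    def test_bifunctional_witness_without_rec_hydrolysis(self):
        """Bifunctional HK-mediated dephosphorylation can stand in for REC
        hydrolysis: sigmoidal witnesses exist at k_h1 = 0."""
        rep = variant_condition_checks("bifunctional_hk", seed=2,
                                       n_draws=500)
        assert rep.passed
        p, _ = rep.witnesses[0]
        assert p.k_h1 == 0.0 and p.k_5 > 0 and p.k_6 > 0

    def test_turnover_witness_confirmed_by_ode(self):
        """The turnover witness's sigmoidality is visible in the numeric
        curve from per-signal ODE steady states."""
        rep = variant_condition_checks("turnover", seed=2, n_draws=2000)
        p, v = rep.witnesses[0]
        top = topology_by_id(3)
        alpha = variant_maximal_response(top, p, v)
        ks_mid = variant_signal_for_response(0.5 * alpha, top, p, v)
        ks_grid = np.linspace(0.05, 1.0, 12) * 2 * ks_mid
        _, rr, _ = variant_steady_curve(top, p, v, ks_grid=ks_grid)
        d2 = np.gradient(np.gradient(rr, ks_grid), ks_grid)
        assert d2[1] > 0  # convex onset confirms the inflection
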