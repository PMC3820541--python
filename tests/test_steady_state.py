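"""Elimination-based signal function against brute-force ODE steady states."""

import numpy as np
import pytest
from dataclasses import replace

from phosphorelay.core_model import ParameterSet, bind_parameters, topology_by_id
from phosphorelay.param_space import SamplingScheme, sample_parameters
from phosphorelay.steady_state import (
    InfeasibleResponse,
    NonResponsiveTopology,
    build_curve,
    eliminate,
    generic_parameters,
    invert_signal,
    is_responsive,
    maximal_response,
    numeric_responsiveness_screen,
    ode_steady_state,
    responsive_topologies,
    signal_for_response,
    steady_state_from_response,
)


def bisect_signal_oracle(topology, params, rr_target, lo=0.0, hi=None,
                         iters=60):
    """Independent oracle: bisect on k_s, integrating the ODE to steady
    state at each candidate, until steady-state RR~P hits the target."""
    if hi is None:
        hi = 1.0
        while ode_steady_state(topology, params, hi)[7] < rr_target:
            hi *= 10.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if ode_steady_state(topology, params, mid)[7] < rr_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSignalForResponse:
    def test_zero_response_zero_signal(self, t30, tuning_params):
        assert signal_for_response(0.0, t30, tuning_params) == 0.0
        hptp, recp, hkp, ks = eliminate(0.0, tuning_params)
        assert (hptp, recp, hkp, ks) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_ks_bisection_oracle(self, t30, tuning_params):
        """f(alpha/2) agrees with bisecting the signal against ODE
        steady states, to 1e-6 relative."""
        alpha = maximal_response(t30, tuning_params)
        rr = 0.5 * alpha
        ks = signal_for_response(rr, t30, tuning_params)
        ks_oracle = bisect_signal_oracle(t30, tuning_params, rr)
        assert ks == pytest.approx(ks_oracle, rel=1e-6)

    def test_no_rr_hydrolysis_reduction(self, t14):
        """With k_h2 = 0 the Hpt~P solve loses its hydrolysis source term
        but f stays positive through REC hydrolysis."""
        p = bind_parameters(t14, ParameterSet(
            k_2=2.0, k_3=1.0, k_4=0.5, k_3r=3.0, k_4r=0.8, k_h1=1.5))
        rr = 0.3 * maximal_response(t14, p)
        hptp, recp, hkp, ks = eliminate(rr, p)
        expected_hptp = (p.k_4r * rr * p.Hpt_tot) / (
            p.k_4 * (p.RR_tot - rr) + p.k_4r * rr)
        assert hptp == pytest.approx(expected_hptp, rel=1e-14)
        assert ks > 0.0

    def test_infeasible_response_rejected(self, t30, tuning_params):
        with pytest.raises(InfeasibleResponse):
            signal_for_response(tuning_params.RR_tot, t30, tuning_params)


class TestMaximalResponse:
    def test_matches_large_signal_ode(self, t30, tuning_params):
        alpha = maximal_response(t30, tuning_params)
        rr_inf = ode_steady_state(t30, tuning_params, 1e6)[7]
        assert alpha == pytest.approx(rr_inf, rel=1e-4)

    def test_scales_with_rr_total(self, t30, tuning_params):
        """alpha vanishes with the RR pool."""
        alphas = []
        for scale in (1.0, 1e-2, 1e-4):
            p = replace(tuning_params, RR_tot=tuning_params.RR_tot * scale)
            alphas.append(maximal_response(t30, p))
        assert alphas[0] > alphas[1] > alphas[2]
        assert alphas[2] < 1e-3 * alphas[0]

    def test_monotone_in_rr_hydrolysis(self, t30, tuning_params):
        """Faster RR~P hydrolysis can only lower the maximal response."""
        alphas = [maximal_response(t30, replace(tuning_params, k_h2=kh2))
                  for kh2 in (1e-3, 1e-2, 1e-1, 1.0, 10.0)]
        assert all(a1 >= a2 - 1e-12 for a1, a2 in zip(alphas, alphas[1:]))
        # spot-check the smallest against the ODE limit
        p = replace(tuning_params, k_h2=10.0)
        assert alphas[-1] == pytest.approx(
            ode_steady_state(t30, p, 1e7)[7], rel=1e-3)

    def test_non_responsive_rejected(self):
        with pytest.raises(NonResponsiveTopology):
            maximal_response(topology_by_id(17),
                             generic_parameters(topology_by_id(17)))


class TestCurve:
    def test_grid_shape_and_monotonicity(self, t30, tuning_params):
        c = build_curve(t30, tuning_params)
        assert len(c) == 96
        assert c.rr_grid[0] == 0.0 and c.ks_values[0] == 0.0
        assert c.rr_grid[-1] == pytest.approx(0.95 * c.alpha)
        assert np.all(np.diff(c.ks_values) > 0)
        assert np.all((c.fraction_grid >= 0) & (c.fraction_grid <= 1))

    def test_grid_points_verified_by_ode(self, t30, tuning_params):
        c = build_curve(t30, tuning_params)
        for i in (10, 48, 90):
            y = ode_steady_state(t30, tuning_params, c.ks_values[i],
                                 tol_factor=1e-11)
            assert y[7] == pytest.approx(c.rr_grid[i], rel=1e-6)

    def test_lower_saturation_with_both_hydrolyses(self, t14, t30):
        """Matched parameters: the topology with RR hydrolysis saturates at
        a lower phosphorylated-RR level."""
        p = ParameterSet(k_2=2.0, k_3=1.0, k_4=0.5, k_3r=3.0, k_4r=0.8,
                         k_h1=1.5, k_h2=1.0)
        a30 = maximal_response(t30, p)
        a14 = maximal_response(t14, replace(p, k_h2=0.0))
        assert a30 < a14

    def test_invert_signal_is_inverse(self, t30, tuning_params):
        alpha = maximal_response(t30, tuning_params)
        for frac in (0.1, 0.5, 0.9):
            ks = signal_for_response(frac * alpha, t30, tuning_params)
            rr = invert_signal(ks, t30, tuning_params, alpha=alpha)
            assert rr == pytest.approx(frac * alpha, rel=1e-9)

    def test_steady_state_vector_is_fixed_point(self, t30, tuning_params):
        from phosphorelay.core_model import ode_rhs
        alpha = maximal_response(t30, tuning_params)
        rr = 0.4 * alpha
        ks = signal_for_response(rr, t30, tuning_params)
        y = steady_state_from_response(t30, tuning_params, rr)
        dy = ode_rhs(0.0, y, replace(tuning_params, k_s=ks))
        assert np.max(np.abs(dy)) < 1e-10 * max(tuning_params.totals)


class TestResponsiveness:
    def test_screen_agrees_with_predicate_generic(self):
        for top in responsive_topologies()[:4] + [topology_by_id(i)
                                                  for i in (9, 17, 21)]:
            assert numeric_responsiveness_screen(top) == is_responsive(top)

    def test_screen_insensitive_to_parameter_draws(self, rng):
        """Responsiveness is structural: random positive rates do not flip
        the screen's verdict."""
        for tid in (14, 9):  # one responsive, one non-responsive
            top = topology_by_id(tid)
            for _ in range(5):
                p = bind_parameters(top, ParameterSet(
                    k_2=rng.uniform(0.3, 3), k_3=rng.uniform(0.3, 3),
                    k_4=rng.uniform(0.3, 3),
                    k_2r=rng.uniform(0.3, 3) if top.r2 else 0,
                    k_3r=rng.uniform(0.3, 3) if top.r3 else 0,
                    k_4r=rng.uniform(0.3, 3) if top.r4 else 0,
                    k_h1=rng.uniform(0.3, 3) if top.h1 else 0,
                    k_h2=rng.uniform(0.3, 3) if top.h2 else 0))
                assert numeric_responsiveness_screen(top, p) == \
                    is_responsive(top)


class TestSampledInstances:
    def test_f_increasing_and_anchored_at_zero(self):
        """For random responsive instances f(0) = 0 and f is strictly
        increasing over its grid."""
        for top in responsive_topologies():
            sets = sample_parameters(SamplingScheme(n_sets=3, seed=top.id),
                                     top)
            for p in sets:
                c = build_curve(top, p)
                assert c.ks_values[0] == 0.0
                assert np.all(np.diff(c.ks_values) > 0)
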