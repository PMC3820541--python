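"""Model variants relaxing the simple relay's assumptions.

Five variants are supported:

* ``bifunctional_hk`` - unphosphorylated HK binds REC~P (rate ``k_5``),
  the complex dissociates (``k_5r``) or catalyzes dephosphorylation
  (``k_6``); the complex is an explicit ninth species.
* ``complexes`` - every phosphotransfer step proceeds through a reversible
  encounter complex with an irreversible transfer step; six additional
  complex species.
* ``turnover`` - production of each unphosphorylated species at rate
  ``delta * X_tot`` and first-order removal of every form at rate ``delta``,
  so steady-state totals remain at ``X_tot`` while phosphorylated forms
  acquire an extra first-order loss.
* ``hk_autodephos`` / ``hpt_autodephos`` - first-order auto-dephosphorylation
  of HK~P (rate ``k_hk``) or Hpt~P (rate ``k_hpt``).

The turnover and auto-dephosphorylation variants reduce exactly, at steady
state, to the simple model's flux-balance elimination with effective rates:
an extra first-order loss on HK~P enters the signal balance, one on Hpt~P
enters the Hpt-layer balance, and losses on REC~P/RR~P add to the hydrolysis
rates.  That gives fast, exact signal functions (and jet derivatives) for
these variants; the bifunctional variant admits a semi-analytic solve with a
one-dimensional root find, and the complexes variant is handled numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import brentq

from ._jet import Jet
from .classification import _pos_to_neg_run
from .core_model import (
    ParameterSet,
    Topology,
    bind_parameters,
    initial_state,
    ode_rhs,
)
from .steady_state import (
    InfeasibleResponse,
    _feasible_mask,
    eliminate,
    integrate_to_steady_state,
)

__all__ = [
    "VariantSpec",
    "variant_rhs",
    "variant_state_size",
    "variant_initial_state",
    "variant_steady_state",
    "variant_steady_curve",
    "effective_parameters",
    "variant_signal_for_response",
    "variant_maximal_response",
    "variant_curvature_at_zero",
    "variant_sign_change",
    "bifunctional_signal_for_response",
    "variant_condition_checks",
]

KINDS = ("bifunctional_hk", "complexes", "turnover",
         "hk_autodephos", "hpt_autodephos")

# encounter-complex channel order for the `complexes` variant
_CHANNELS = ("fwd2", "fwd3", "fwd4", "rev2", "rev3", "rev4")


@dataclass(frozen=True)
class VariantSpec:
    """Which relaxation is active and its extra rate constants."""

    kind: str
    delta: float = 0.0          # turnover: production/removal rate
    k_hk: float = 0.0           # hk_autodephos: HK~P -> HK
    k_hpt: float = 0.0          # hpt_autodephos: Hpt~P -> Hpt
    # complexes: on/off/cat rates per channel (fwd2, fwd3, fwd4, rev2,
    # rev3, rev4); zero on-rate disables the channel
    on_rates: tuple = (0.0,) * 6
    off_rates: tuple = (0.0,) * 6
    cat_rates: tuple = (0.0,) * 6

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @staticmethod
    def complexes_matching(topology: Topology, params: ParameterSet,
                           off: float = 100.0, cat: float = 100.0,
                           ) -> "VariantSpec":
        """Encounter-complex rates whose net transfer rate equals the simple
        model's: on = k * (off + cat) / cat for each present channel."""
        p = bind_parameters(topology, params)
        ks_simple = (p.k_2, p.k_3, p.k_4, p.k_2r, p.k_3r, p.k_4r)
        on = tuple(k * (off + cat) / cat for k in ks_simple)
        offs = tuple(off if k > 0 else 0.0 for k in ks_simple)
        cats = tuple(cat if k > 0 else 0.0 for k in ks_simple)
        return VariantSpec("complexes", on_rates=on, off_rates=offs,
                           cat_rates=cats)


def variant_state_size(variant: VariantSpec) -> int:
    if variant.kind == "bifunctional_hk":
        return 9
    if variant.kind == "complexes":
        return 14
    return 8


def variant_initial_state(params: ParameterSet, variant: VariantSpec
                          ) -> np.ndarray:
    y = initial_state(params)
    extra = variant_state_size(variant) - 8
    return np.concatenate([y, np.zeros(extra)]) if extra else y


def variant_rhs(t, y, params: ParameterSet, variant: VariantSpec):
    """Mass-action right-hand side for the selected variant."""
    p = params
    if variant.kind == "bifunctional_hk":
        HK, HKp, REC, RECp, Hpt, Hptp, RR, RRp, C = y
        auto = p.k_s * HK
        j2 = p.k_2 * HKp * REC - p.k_2r * HK * RECp
        j3 = p.k_3 * RECp * Hpt - p.k_3r * REC * Hptp
        j4 = p.k_4 * Hptp * RR - p.k_4r * RRp * Hpt
        h1 = p.k_h1 * RECp
        h2 = p.k_h2 * RRp
        bind = p.k_5 * HK * RECp
        unbind = p.k_5r * C
        cat = p.k_6 * C
        return np.array([
            -auto + j2 - bind + unbind + cat,
            auto - j2,
            -j2 + j3 + h1 + cat,
            j2 - j3 - h1 - bind + unbind,
            -j3 + j4,
            j3 - j4,
            -j4 + h2,
            j4 - h2,
            bind - unbind - cat,
        ])
    if variant.kind == "complexes":
        return _complexes_rhs(y, p, variant)
    # 8-species variants share the simple skeleton
    dy = ode_rhs(t, y, p)
    HK, HKp, REC, RECp, Hpt, Hptp, RR, RRp = y
    if variant.kind == "turnover":
        d = variant.delta
        prod = np.array([p.HK_tot, 0.0, p.REC_tot, 0.0,
                         p.Hpt_tot, 0.0, p.RR_tot, 0.0]) * d
        dy = dy + prod - d * np.asarray(y)
    elif variant.kind == "hk_autodephos":
        dy[0] += variant.k_hk * HKp
        dy[1] -= variant.k_hk * HKp
    elif variant.kind == "hpt_autodephos":
        dy[4] += variant.k_hpt * Hptp
        dy[5] -= variant.k_hpt * Hptp
    return dy


def _complexes_rhs(y, p, variant):
    HK, HKp, REC, RECp, Hpt, Hptp, RR, RRp = y[:8]
    C = y[8:]  # order follows _CHANNELS
    a, b, c = variant.on_rates, variant.off_rates, variant.cat_rates
    pairs = (  # (substrate product for on-reaction, products of catalysis)
        (HKp * REC,), (RECp * Hpt,), (Hptp * RR,),
        (HK * RECp,), (REC * Hptp,), (Hpt * RRp,),
    )
    on = np.array([a[i] * pairs[i][0] for i in range(6)])
    off = np.array([b[i] * C[i] for i in range(6)])
    cat = np.array([c[i] * C[i] for i in range(6)])
    h1 = p.k_h1 * RECp
    h2 = p.k_h2 * RRp
    auto = p.k_s * HK
    dHK = -auto + cat[0] - on[3] + off[3]
    dHKp = auto - on[0] + off[0] + cat[3]
    dREC = -on[0] + off[0] + cat[1] + cat[3] - on[4] + off[4] + h1
    dRECp = cat[0] - on[1] + off[1] - on[3] + off[3] + cat[4] - h1
    dHpt = -on[1] + off[1] + cat[2] + cat[4] - on[5] + off[5]
    dHptp = cat[1] - on[2] + off[2] - on[4] + off[4] + cat[5]
    dRR = -on[2] + off[2] + cat[5] + h2
    dRRp = cat[2] - on[5] + off[5] - h2
    dC = on - off - cat
    return np.concatenate([[dHK, dHKp, dREC, dRECp, dHpt, dHptp, dRR, dRRp],
                           dC])


def variant_conservation(y, params: ParameterSet, variant: VariantSpec
                         ) -> np.ndarray:
    """Per-layer totals including complex species (turnover excluded)."""
    y = np.asarray(y)
    if variant.kind == "bifunctional_hk":
        C = y[8]
        return np.array([y[0] + y[1] + C, y[2] + y[3] + C,
                         y[4] + y[5], y[6] + y[7]])
    if variant.kind == "complexes":
        C = y[8:]
        return np.array([
            y[0] + y[1] + C[0] + C[3],
            y[2] + y[3] + C[0] + C[3] + C[1] + C[4],
            y[4] + y[5] + C[1] + C[4] + C[2] + C[5],
            y[6] + y[7] + C[2] + C[5],
        ])
    return np.array([y[0] + y[1], y[2] + y[3], y[4] + y[5], y[6] + y[7]])


def variant_steady_state(topology: Topology, params: ParameterSet,
                         variant: VariantSpec, ks: float,
                         y0=None, tol_factor: float = 1e-9) -> np.ndarray:
    """Steady state of the variant ODE at signal *ks* by stiff integration."""
    p = bind_parameters(topology, params)
    p = dc_replace(p, k_s=ks)
    if y0 is None:
        y0 = variant_initial_state(p, variant)
    scale = max(p.totals)

    def rhs(t, y):
        return variant_rhs(t, y, p, variant)

    return integrate_to_steady_state(rhs, y0, scale, tol_factor=tol_factor)


def variant_steady_curve(topology: Topology, params: ParameterSet,
                         variant: VariantSpec, ks_grid=None,
                         n_signals: int = 25, ks_large: float = 1e6):
    """Numeric signal-response curve: per-signal ODE steady states.

    Returns ``(ks_grid, rr_values, alpha)`` with alpha estimated from the
    large-signal limit.  When no grid is given, signals are log-spaced over
    four decades below the signal at which the response is near-saturated.
    """
    p = bind_parameters(topology, params)
    y_inf = variant_steady_state(topology, p, variant, ks_large)
    alpha = float(y_inf[7])
    if ks_grid is None:
        # find a signal giving ~90% of alpha by doubling, then span 4 decades
        ks_hi = 1e-6
        for _ in range(60):
            y = variant_steady_state(topology, p, variant, ks_hi)
            if y[7] >= 0.9 * alpha:
                break
            ks_hi *= 2.0
        ks_grid = np.logspace(math.log10(ks_hi) - 4, math.log10(ks_hi),
                              n_signals)
    rr = []
    y = None
    for ks in ks_grid:
        y = variant_steady_state(topology, p, variant, ks, y0=y)
        rr.append(float(y[7]))
    return np.asarray(ks_grid, dtype=float), np.asarray(rr), alpha


# ---------------------------------------------------------------------------
# steady-state elimination for the 8-species variants (exact)

def effective_parameters(topology: Topology, params: ParameterSet,
                         variant: VariantSpec):
    """Map an 8-species variant onto the generalized elimination.

    Returns ``(p_eff, kh0, kh3)``: parameters with hydrolysis rates absorbed
    into effective values plus the first-order losses on HK~P (``kh0``) and
    Hpt~P (``kh3``).  Only valid for turnover and auto-dephosphorylation
    variants (the steady-state flux balances are then formally identical to
    the simple model's).
    """
    p = bind_parameters(topology, params)
    if variant.kind == "turnover":
        d = variant.delta
        return dc_replace(p, k_h1=p.k_h1 + d, k_h2=p.k_h2 + d), d, d
    if variant.kind == "hk_autodephos":
        return p, variant.k_hk, 0.0
    if variant.kind == "hpt_autodephos":
        return p, 0.0, variant.k_hpt
    raise ValueError(
        f"variant {variant.kind!r} has no simple-model elimination form"
    )


def variant_signal_for_response(rr, topology: Topology, params: ParameterSet,
                                variant: VariantSpec):
    """Exact f(rr) for turnover / auto-dephosphorylation variants."""
    p_eff, kh0, kh3 = effective_parameters(topology, params, variant)
    ok, ks = _feasible_mask(float(rr), p_eff, kh0, kh3)
    if not ok:
        raise InfeasibleResponse(f"rr={rr} infeasible under {variant.kind}")
    return float(np.maximum(ks, 0.0))


def variant_maximal_response(topology: Topology, params: ParameterSet,
                             variant: VariantSpec, rtol: float = 1e-10
                             ) -> float:
    """alpha for the 8-species variants by feasibility bisection."""
    p_eff, kh0, kh3 = effective_parameters(topology, params, variant)
    lo, hi = 0.0, p_eff.RR_tot
    if bool(_feasible_mask(hi, p_eff, kh0, kh3)[0]):
        return hi
    while hi - lo > rtol * p_eff.RR_tot:
        mid = 0.5 * (lo + hi)
        if bool(_feasible_mask(mid, p_eff, kh0, kh3)[0]):
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        raise InfeasibleResponse("no feasible response under this variant")
    return 0.5 * (lo + hi)


def variant_curvature_at_zero(topology: Topology, params: ParameterSet,
                              variant: VariantSpec) -> float:
    """Curvature of the response curve at zero signal for 8-species variants."""
    p_eff, kh0, kh3 = effective_parameters(topology, params, variant)
    jet = Jet.variable(0.0)
    *_, ks = eliminate(jet, p_eff, kh0, kh3)
    if not (ks.d1 > 0.0) or not math.isfinite(ks.d1):
        raise InfeasibleResponse("degenerate flat start (f'(0) <= 0)")
    return -ks.d2 / ks.d1 ** 3


def variant_sign_change(topology: Topology, params: ParameterSet,
                        variant: VariantSpec, n_grid: int = 200) -> bool:
    """Whole-curve sign-change classification for 8-species variants."""
    p_eff, kh0, kh3 = effective_parameters(topology, params, variant)
    alpha = variant_maximal_response(topology, params, variant)
    rr_pts = np.linspace(0.0, 0.95 * alpha, n_grid + 1)[1:]
    jet = Jet.variable(rr_pts)
    *_, ksj = eliminate(jet, p_eff, kh0, kh3)
    curv = -ksj.d2 / ksj.d1 ** 3
    return _pos_to_neg_run(np.sign(curv), 2)


# ---------------------------------------------------------------------------
# bifunctional HK: semi-analytic signal function

def bifunctional_signal_for_response(rr: float, topology: Topology,
                                     params: ParameterSet) -> float:
    """f(rr) for the bifunctional-HK model.

    The HK-REC~P complex is at steady state (C = k_5 HK RECp / (k_5r+k_6)),
    the Hpt and RR layer balances are unchanged, and the coupled REC/HK
    layer balance reduces to a one-dimensional root find.  Raises
    :class:`InfeasibleResponse` outside the feasible domain.
    """
    p = bind_parameters(topology, params)
    if p.k_5 <= 0 or (p.k_5r + p.k_6) <= 0:
        raise ValueError("bifunctional variant requires k_5 > 0 and "
                         "k_5r + k_6 > 0")
    rr = float(rr)
    if rr == 0.0:
        return 0.0
    q = p.k_5 / (p.k_5r + p.k_6)
    hptp = (rr * (p.k_h2 + p.k_4r * p.Hpt_tot)) / (
        p.k_4 * (p.RR_tot - rr) + p.k_4r * rr)
    if not (0.0 <= hptp <= p.Hpt_tot):
        raise InfeasibleResponse("Hpt~P outside its range")
    j3 = p.k_h2 * rr

    if p.k_3r * hptp > 0.0:
        # C follows from the Hpt-layer balance once REC~P is chosen
        def complex_of(recp):
            return (p.REC_tot - recp
                    - (p.k_3 * recp * (p.Hpt_tot - hptp) - j3)
                    / (p.k_3r * hptp))

        def residual(recp):
            C = complex_of(recp)
            HK = C / (q * recp)
            HKp = p.HK_tot - HK - C
            rec_free = p.REC_tot - recp - C
            j2 = p.k_2 * HKp * rec_free - p.k_2r * HK * recp
            return j2 - j3 - p.k_h1 * recp - p.k_6 * C

        # the complex concentration decreases with REC~P; the physical root
        # lies between the REC-depletion point (free REC = 0) and the point
        # where the complex vanishes
        denom = 1.0 + p.k_3 * (p.Hpt_tot - hptp) / (p.k_3r * hptp)
        recp_max = min(p.REC_tot,
                       (p.REC_tot + j3 / (p.k_3r * hptp)) / denom)
        recp_min = j3 / (p.k_3 * (p.Hpt_tot - hptp)) \
            if p.k_3 * (p.Hpt_tot - hptp) > 0 else 0.0
        if not (recp_min < recp_max):
            raise InfeasibleResponse("no steady state at this response level")
        span = recp_max - recp_min
        # scan for a sign change, then polish with Brent's method
        us = np.concatenate([np.geomspace(1e-12, 0.5, 40),
                             1.0 - np.geomspace(1e-12, 0.5, 40)[::-1]])
        grid = recp_min + span * us
        vals = np.array([residual(x) for x in grid])
        finite = np.isfinite(vals)
        sign_flip = None
        for i in range(len(grid) - 1):
            if finite[i] and finite[i + 1] and vals[i] * vals[i + 1] <= 0:
                sign_flip = i
                break
        if sign_flip is None:
            raise InfeasibleResponse("no steady state at this response level")
        recp = brentq(residual, grid[sign_flip], grid[sign_flip + 1],
                      xtol=1e-18 * recp_max, rtol=4 * np.finfo(float).eps,
                      maxiter=200)
        C = complex_of(recp)
        HK = C / (q * recp)
    else:
        # no reverse transfer at layer 2-3: REC~P decouples
        recp = j3 / (p.k_3 * (p.Hpt_tot - hptp))

        def residual_hk(HK):
            C = q * HK * recp
            HKp = p.HK_tot - HK - C
            rec_free = p.REC_tot - recp - C
            j2 = p.k_2 * HKp * rec_free - p.k_2r * HK * recp
            return j2 - j3 - p.k_h1 * recp - p.k_6 * C

        lo, hi = 1e-14 * p.HK_tot, p.HK_tot * (1.0 - 1e-12)
        flo, fhi = residual_hk(lo), residual_hk(hi)
        if flo * fhi > 0:
            raise InfeasibleResponse("no steady state at this response level")
        HK = brentq(residual_hk, lo, hi, xtol=1e-18 * p.HK_tot,
                    rtol=4 * np.finfo(float).eps, maxiter=200)
        C = q * HK * recp

    HKp = p.HK_tot - HK - C
    if not (0.0 <= recp <= p.REC_tot and 0.0 <= C and HK > 0.0
            and 0.0 <= HKp <= p.HK_tot):
        raise InfeasibleResponse("intermediate outside its range")
    ks = (j3 + p.k_h1 * recp + p.k_6 * C) / HK
    if not np.isfinite(ks) or ks < 0:
        raise InfeasibleResponse("signal not finite at this response level")
    return float(ks)


def bifunctional_curve_classify(topology: Topology, params: ParameterSet,
                                n_grid: int = 120) -> bool:
    """True iff the bifunctional signal-response curve is sigmoidal.

    Uses the numeric sign-change criterion on the semi-analytic signal
    function (second differences of response against a uniform signal grid).
    """
    alpha = _bifunctional_alpha(topology, params)
    rr_hi = 0.95 * alpha
    ks_max = bifunctional_signal_for_response(rr_hi, topology, params)
    ks_grid = np.linspace(0.0, ks_max, n_grid + 1)[1:]
    rr_pts = [_bif_invert(k, topology, params, rr_hi) for k in ks_grid]
    d1 = np.gradient(rr_pts, ks_grid)
    d2 = np.gradient(d1, ks_grid)
    return _pos_to_neg_run(np.sign(d2[1:-1]), 2)


def _bif_feasible(rr, topology, params) -> bool:
    try:
        bifunctional_signal_for_response(rr, topology, params)
        return True
    except InfeasibleResponse:
        return False


def _bifunctional_alpha(topology: Topology, params: ParameterSet,
                        rtol: float = 1e-10) -> float:
    p = bind_parameters(topology, params)
    lo, hi = 0.0, p.RR_tot
    if _bif_feasible(hi, topology, p):
        return hi
    while hi - lo > rtol * p.RR_tot:
        mid = 0.5 * (lo + hi)
        if _bif_feasible(mid, topology, p):
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        raise InfeasibleResponse("no feasible bifunctional response found")
    return 0.5 * (lo + hi)


def _bif_invert(ks, topology, params, rr_hi, iters: int = 55) -> float:
    lo, hi = 0.0, rr_hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        try:
            val = bifunctional_signal_for_response(mid, topology, params)
            if val < ks:
                lo = mid
                continue
        except InfeasibleResponse:
            pass
        hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# randomized checks of the variant-specific sigmoidality claims

@dataclass(frozen=True)
class ConditionCheckReport:
    kind: str
    claim: str
    n_draws: int
    witnesses: list
    counterexamples: list
    passed: bool


def _loguni(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def variant_condition_checks(kind: str, seed: int = 0, n_draws: int = 10_000
                             ) -> ConditionCheckReport:
    """Randomized existence/necessity checks for a variant's claims.

    * ``hpt_autodephos``: with k_h1 = k_3r = 0 and k_4r > k_4, sigmoidal
      instances exist (witness search).
    * ``turnover``: with k_h1 = k_3r = 0 and k_4r > 0, sigmoidal instances
      exist (witness search).
    * ``hk_autodephos``: no sigmoidal instance violates the simple model's
      necessary conditions (counterexample search over ``n_draws`` draws).
    * ``bifunctional_hk``: topologies lacking hydrolysis at REC (k_h1 = 0)
      can exhibit sigmoidality (witness search).
    """
    from .core_model import topology_by_id

    rng = np.random.default_rng(seed)
    witnesses: list = []
    counterexamples: list = []

    if kind == "hpt_autodephos":
        claim = "sigmoidality with k_h1 = k_3r = 0 and k_4r > k_4"
        top = topology_by_id(3)  # rev (0,0,1), hyd (0,1)
        for i in range(n_draws):
            k_4 = _loguni(rng, 1e-2, 1e2)
            p = ParameterSet(
                k_2=_loguni(rng, 1e-2, 1e2), k_3=_loguni(rng, 1e-2, 1e2),
                k_4=k_4, k_4r=k_4 * _loguni(rng, 1.5, 1e2),
                k_h2=_loguni(rng, 1e-3, 1e1))
            v = VariantSpec("hpt_autodephos", k_hpt=_loguni(rng, 1e-3, 1e1))
            try:
                if (variant_curvature_at_zero(top, p, v) > 0
                        and variant_sign_change(top, p, v)):
                    witnesses.append((p, v))
                    break
            except (InfeasibleResponse, ValueError):
                continue
        return ConditionCheckReport(kind, claim, i + 1, witnesses, [],
                                    bool(witnesses))

    if kind == "turnover":
        claim = "sigmoidality with k_h1 = k_3r = 0 and k_4r > 0"
        top = topology_by_id(3)
        for i in range(n_draws):
            p = ParameterSet(
                k_2=_loguni(rng, 1e-2, 1e2), k_3=_loguni(rng, 1e-2, 1e2),
                k_4=_loguni(rng, 1e-2, 1e2), k_4r=_loguni(rng, 1e-2, 1e2),
                k_h2=_loguni(rng, 1e-3, 1e1))
            v = VariantSpec("turnover", delta=_loguni(rng, 1e-3, 1e1))
            try:
                if (variant_curvature_at_zero(top, p, v) > 0
                        and variant_sign_change(top, p, v)):
                    witnesses.append((p, v))
                    break
            except (InfeasibleResponse, ValueError):
                continue
        return ConditionCheckReport(kind, claim, i + 1, witnesses, [],
                                    bool(witnesses))

    if kind == "hk_autodephos":
        from .classification import necessary_conditions

        claim = ("no sigmoidal instance violates the simple model's "
                 "necessary conditions")
        # full-conditions search on the all-reactions topology plus the
        # structurally forced-zero cases (no REC hydrolysis; no REC-Hpt
        # reverse transfer)
        cases = (topology_by_id(32), topology_by_id(8), topology_by_id(28))
        per_case = max(1, n_draws // len(cases))
        for top in cases:
            for _ in range(per_case):
                p = ParameterSet(
                    k_2=_loguni(rng, 1e-2, 1e2), k_3=_loguni(rng, 1e-2, 1e2),
                    k_4=_loguni(rng, 1e-2, 1e2),
                    k_2r=_loguni(rng, 1e-2, 1e2) if top.r2 else 0.0,
                    k_3r=_loguni(rng, 1e-2, 1e2) if top.r3 else 0.0,
                    k_4r=_loguni(rng, 1e-2, 1e2) if top.r4 else 0.0,
                    k_h1=_loguni(rng, 1e-3, 1e1) if top.h1 else 0.0,
                    k_h2=_loguni(rng, 1e-3, 1e1))
                v = VariantSpec("hk_autodephos", k_hk=_loguni(rng, 1e-3, 1e1))
                try:
                    sig = variant_curvature_at_zero(top, p, v) > 0
                except (InfeasibleResponse, ValueError):
                    continue
                if sig and not necessary_conditions(p)[0]:
                    counterexamples.append((top.id, p, v))
        return ConditionCheckReport(kind, claim, per_case * len(cases), [],
                                    counterexamples, not counterexamples)

    if kind == "bifunctional_hk":
        claim = "sigmoidality in a topology lacking hydrolysis at REC"
        top = topology_by_id(8)  # rev (1,1,1), hyd (0,1): k_h1 = 0
        for i in range(n_draws):
            p = ParameterSet(
                k_2=_loguni(rng, 1e-2, 1e2), k_3=_loguni(rng, 1e-2, 1e2),
                k_4=_loguni(rng, 1e-2, 1e2), k_2r=_loguni(rng, 1e-4, 1e-1),
                k_3r=_loguni(rng, 1e-2, 1e2), k_4r=_loguni(rng, 1e-2, 1e2),
                k_h2=_loguni(rng, 1e-3, 1e1),
                k_5=_loguni(rng, 1e-1, 1e3), k_5r=_loguni(rng, 1e-3, 1e1),
                k_6=_loguni(rng, 1e-2, 1e2))
            try:
                if bifunctional_curve_classify(top, p):
                    witnesses.append((p, None))
                    break
            except (InfeasibleResponse, ValueError, RuntimeError):
                continue
        return ConditionCheckReport(kind, claim, i + 1, witnesses, [],
                                    bool(witnesses))

    raise ValueError(f"no condition checks defined for {kind!r}")
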