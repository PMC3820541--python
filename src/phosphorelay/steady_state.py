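"""Steady-state signal-response analysis of the four-layered relay.

At steady state the phosphoryl flux through each layer balances the losses
below it, so the whole fixed-point problem collapses to a chain of linear
solves: given the output ``rr`` = [RR~P], the Hpt-layer balance determines
[Hpt~P], then the REC-layer balance determines [REC~P], then the HK-layer
balance determines [HK~P], and finally the signal follows as
``k_s = f(rr)``.  The function f is strictly increasing on ``[0, alpha)``
and diverges at the maximal response alpha, the supremum of steady-state
RR~P over all signals; the signal-response curve is the inverse of f.

The elimination accepts floats, numpy arrays or :class:`~phosphorelay._jet.Jet`
objects, so the same code path yields curves, vectorized grids and exact
derivatives.  Optional first-order loss terms on HK~P (``kh0``) and Hpt~P
(``kh3``) extend the same chain to the auto-dephosphorylation and turnover
model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import (
    ParameterSet,
    Topology,
    bind_parameters,
    enumerate_topologies,
    initial_state,
    ode_rhs,
    state_from_phospho,
)

__all__ = [
    "InfeasibleResponse",
    "NonResponsiveTopology",
    "SteadyStateNotReached",
    "SignalResponseCurve",
    "eliminate",
    "signal_for_response",
    "signal_for_response_grid",
    "maximal_response",
    "invert_signal",
    "build_curve",
    "is_responsive",
    "generic_parameters",
    "numeric_responsiveness_screen",
    "integrate_to_steady_state",
    "ode_steady_state",
]


class InfeasibleResponse(ValueError):
    """The requested RR~P level is not attainable (it lies at or above alpha)."""


class NonResponsiveTopology(ValueError):
    """The topology's output jumps to its maximum for any non-zero signal."""


class SteadyStateNotReached(RuntimeError):
    """ODE integration did not satisfy the derivative-norm criterion in time."""


def eliminate(rr, p: ParameterSet, kh0=0.0, kh3=0.0):
    """Sequential flux-balance solves; returns ``(Hptp, RECp, HKp, ks)``.

    No feasibility checks are performed here - callers decide how to treat
    intermediates outside ``[0, total]``.  ``kh0``/``kh3`` are optional
    first-order loss rates on HK~P and Hpt~P used by the model variants.
    """
    # RR-layer balance: k4*Hptp*(RRt-rr) - k4r*rr*(Hptt-Hptp) = kh2*rr
    hptp = (rr * (p.k_h2 + p.k_4r * p.Hpt_tot)) / (
        p.k_4 * (p.RR_tot - rr) + p.k_4r * rr
    )
    j3 = p.k_h2 * rr + kh3 * hptp
    # Hpt-layer balance: k3*RECp*(Hptt-Hptp) - k3r*(RECt-RECp)*Hptp = j3
    recp = (j3 + p.k_3r * p.REC_tot * hptp) / (
        p.k_3 * (p.Hpt_tot - hptp) + p.k_3r * hptp
    )
    j2 = j3 + p.k_h1 * recp
    # REC-layer balance: k2*HKp*(RECt-RECp) - k2r*(HKt-HKp)*RECp = j2
    hkp = (j2 + p.k_2r * p.HK_tot * recp) / (
        p.k_2 * (p.REC_tot - recp) + p.k_2r * recp
    )
    ks = (j2 + kh0 * hkp) / (p.HK_tot - hkp)
    return hptp, recp, hkp, ks


def _feasible_mask(rr, p: ParameterSet, kh0=0.0, kh3=0.0):
    """Vectorized feasibility of the elimination at each ``rr`` plus ks values."""
    rr = np.asarray(rr, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hptp, recp, hkp, ks = eliminate(rr, p, kh0, kh3)
    eps = 1e-12
    ok = (rr >= 0) & (rr <= p.RR_tot)
    for val, tot in ((hptp, p.Hpt_tot), (recp, p.REC_tot)):
        ok &= np.isfinite(val) & (val >= -eps * tot) & (val <= tot * (1 + eps))
    ok &= np.isfinite(hkp) & (hkp >= -eps * p.HK_tot) & (hkp < p.HK_tot)
    ok &= np.isfinite(ks) & (ks >= -eps)
    return ok, ks


def signal_for_response(rr: float, topology: Topology, params: ParameterSet,
                        kh0: float = 0.0, kh3: float = 0.0) -> float:
    """The signal ``k_s = f(rr)`` sustaining steady-state RR~P level *rr*.

    Raises :class:`InfeasibleResponse` when some intermediate concentration
    leaves its physical range, which signals ``rr >= alpha``.
    """
    p = bind_parameters(topology, params)
    ok, ks = _feasible_mask(float(rr), p, kh0, kh3)
    if not ok:
        raise InfeasibleResponse(
            f"rr={rr} is not a feasible steady-state response for {topology}"
        )
    return float(np.maximum(ks, 0.0))


def signal_for_response_grid(rr, topology: Topology, params: ParameterSet,
                             kh0: float = 0.0, kh3: float = 0.0) -> np.ndarray:
    """Vectorized f over an array of responses; infeasible entries are NaN."""
    p = bind_parameters(topology, params)
    ok, ks = _feasible_mask(rr, p, kh0, kh3)
    return np.where(ok, np.maximum(ks, 0.0), np.nan)


def is_responsive(topology: Topology) -> bool:
    """Structural responsiveness predicate.

    A topology is non-responsive - its output jumps to the maximum for any
    positive signal - exactly when RR~P is not hydrolyzed and, additionally,
    either REC~P is not hydrolyzed or one of the two lower reverse transfers
    is absent.
    """
    return not (not topology.h2 and (not topology.h1 or not topology.r3
                                     or not topology.r4))


def maximal_response(topology: Topology, params: ParameterSet,
                     rtol: float = 1e-10, kh0: float = 0.0,
                     kh3: float = 0.0) -> float:
    """Maximal steady-state RR~P, located by feasibility bisection.

    alpha is the boundary of the domain of f, i.e. the large-signal limit of
    the steady-state response; f diverges as rr -> alpha.
    """
    if not is_responsive(topology) and kh0 == 0.0 and kh3 == 0.0:
        raise NonResponsiveTopology(
            f"{topology} is non-responsive; alpha is attained at any positive signal"
        )
    p = bind_parameters(topology, params)

    def feasible(x):
        return bool(_feasible_mask(x, p, kh0, kh3)[0])

    lo, hi = 0.0, p.RR_tot
    if feasible(hi):
        return hi
    while hi - lo > rtol * p.RR_tot:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        raise InfeasibleResponse(
            f"no feasible response found for {topology} (alpha ~ 0)"
        )
    return 0.5 * (lo + hi)


def invert_signal(ks: float, topology: Topology, params: ParameterSet,
                  alpha: float | None = None, rtol: float = 1e-12,
                  kh0: float = 0.0, kh3: float = 0.0) -> float:
    """Steady-state RR~P at signal *ks*: the inverse of f by bisection."""
    if ks < 0:
        raise ValueError("signal must be >= 0")
    if ks == 0.0:
        return 0.0
    p = bind_parameters(topology, params)
    if alpha is None:
        alpha = maximal_response(topology, params, kh0=kh0, kh3=kh3)

    # expand the bracket toward alpha until f(hi) >= ks (f diverges at alpha)
    hi = 0.95 * alpha
    while True:
        ok, val = _feasible_mask(hi, p, kh0, kh3)
        if ok and val < ks:
            hi = alpha - 0.5 * (alpha - hi)
            if alpha - hi < 1e-15 * alpha:
                return hi
        else:
            break
    lo = 0.0
    while hi - lo > rtol * max(hi, 1e-300):
        mid = 0.5 * (lo + hi)
        ok, val = _feasible_mask(mid, p, kh0, kh3)
        if ok and val < ks:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class SignalResponseCurve:
    """Sampled signal-response relation for one topology + parameter set.

    The grid runs from 0 to 0.95*alpha in steps of alpha/100 (96 points,
    including zero).  ``ks_values`` are the matching signals f(rr); plotted
    with signal on x and response on y the curve is the system's
    dose-response relationship.
    """

    rr_grid: np.ndarray
    ks_values: np.ndarray
    alpha: float
    topology: Topology
    params: ParameterSet

    @property
    def fraction_grid(self) -> np.ndarray:
        """Response as a fraction of total RR."""
        return self.rr_grid / self.params.RR_tot

    def __len__(self) -> int:
        return len(self.rr_grid)


def build_curve(topology: Topology, params: ParameterSet) -> SignalResponseCurve:
    """Signal-response curve on the standard 96-point grid ``0 .. 0.95*alpha``."""
    p = bind_parameters(topology, params)
    alpha = maximal_response(topology, p)
    rr = alpha * np.arange(96) / 100.0
    ks = signal_for_response_grid(rr, topology, p)
    if np.any(~np.isfinite(ks)):
        raise InfeasibleResponse(
            f"curve grid contains infeasible points for {topology}"
        )
    if np.any(np.diff(ks) <= 0):
        raise InfeasibleResponse(
            f"f is not strictly increasing on the grid for {topology}"
        )
    return SignalResponseCurve(rr, ks, alpha, topology, p)


def generic_parameters(topology: Topology) -> ParameterSet:
    """All present rates and totals set to one (structural screening values)."""
    return ParameterSet(
        k_2=1.0, k_3=1.0, k_4=1.0,
        k_2r=1.0 if topology.r2 else 0.0,
        k_3r=1.0 if topology.r3 else 0.0,
        k_4r=1.0 if topology.r4 else 0.0,
        k_h1=1.0 if topology.h1 else 0.0,
        k_h2=1.0 if topology.h2 else 0.0,
    )


def integrate_to_steady_state(rhs, y0, scale: float, tol_factor: float = 1e-9,
                              t_init: float = 10.0, max_doublings: int = 40,
                              rtol: float = 1e-8, atol_factor: float = 1e-12):
    """Integrate ``rhs`` until ``max |dy/dt| < tol_factor * scale``.

    The horizon doubles until the derivative-norm criterion is met.  Returns
    the final state.  Raises :class:`SteadyStateNotReached` on failure.
    """
    y = np.asarray(y0, dtype=float)
    tol = tol_factor * scale
    atol = atol_factor * scale
    t_span = t_init
    if np.max(np.abs(rhs(0.0, y))) < tol:
        return y
    for _ in range(max_doublings):
        sol = solve_ivp(rhs, (0.0, t_span), y, method="LSODA",
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise SteadyStateNotReached(sol.message)
        y = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, y))) < tol:
            return y
        t_span *= 2.0
    raise SteadyStateNotReached(
        f"derivative norm still above {tol} after horizon {t_span}"
    )


def ode_steady_state(topology: Topology, params: ParameterSet, ks: float,
                     y0=None, tol_factor: float = 1e-9,
                     polish: bool = False) -> np.ndarray:
    """Steady state of the simple model at signal *ks* by stiff integration.

    This is the brute-force counterpart of the elimination formulas and is
    used as an independent check throughout the test-suite.  With
    ``polish=True`` the integrated endpoint seeds a Newton solve of the full
    nonlinear fixed-point system (the four phospho-form balances under the
    conservation constraints), removing the residual drift that the
    derivative-norm stopping criterion leaves on stiff instances.
    """
    p = bind_parameters(topology, params)
    if p.k_s != ks:
        p = dc_replace(p, k_s=ks)
    if y0 is None:
        y0 = initial_state(p)
    scale = max(p.totals)

    def rhs(t, y):
        return ode_rhs(t, y, p)

    y = integrate_to_steady_state(rhs, y0, scale, tol_factor=tol_factor)
    if polish:
        from scipy.optimize import root

        def residual(phos):
            full = state_from_phospho(p, *phos)
            return ode_rhs(0.0, full, p)[1::2]

        sol = root(residual, y[1::2], method="hybr", tol=1e-14)
        cand = sol.x
        tots = np.array(p.totals)
        # judge by the achieved residual, not the solver's success flag
        # (hybr under-reports success at very small residual scales)
        improved = (np.max(np.abs(residual(cand)))
                    <= np.max(np.abs(residual(y[1::2]))))
        ok = (improved
              and np.all(cand >= -1e-12 * tots) and np.all(cand <= tots)
              and np.max(np.abs(cand - y[1::2])) < 1e-3 * scale)
        if ok:
            y = state_from_phospho(p, *np.clip(cand, 0.0, tots))
    return y


def numeric_responsiveness_screen(topology: Topology,
                                  params: ParameterSet | None = None,
                                  signals=(1e-6, 1.0),
                                  threshold: float = 0.01) -> bool:
    """Numerical responsiveness test at two widely separated signal levels.

    Integrates the ODE to steady state at each signal and reports responsive
    iff the steady-state RR~P levels differ by more than ``threshold`` of
    total RR.  With generic positive parameters this must agree with
    :func:`is_responsive` on all 32 topologies.
    """
    p = params if params is not None else generic_parameters(topology)
    lo, hi = signals
    y_lo = ode_steady_state(topology, p, lo)
    y_hi = ode_steady_state(topology, p, hi)
    return abs(y_hi[7] - y_lo[7]) > threshold * p.RR_tot


def steady_state_from_response(topology: Topology, params: ParameterSet,
                               rr: float) -> np.ndarray:
    """Full steady-state vector at response level *rr* via the elimination."""
    p = bind_parameters(topology, params)
    hptp, recp, hkp, _ = eliminate(float(rr), p)
    return state_from_phospho(p, float(hkp), float(recp), float(hptp), float(rr))


def responsive_topologies() -> list[Topology]:
    """The 18 responsive topologies, in id order."""
    return [t for t in enumerate_topologies() if is_responsive(t)]
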