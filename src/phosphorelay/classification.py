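"""Hyperbolic vs. sigmoidal classification of signal-response curves.

A hyperbolic dose-response curve is concave throughout (second derivative of
response with respect to signal negative everywhere), while a sigmoidal curve
starts convex and passes through an inflection point.  Two classifiers are
provided:

* **curvature at zero** - the sign of d2(RR~P)/dks2 at ks = 0, obtained from
  exact derivatives of the elimination function f via the inverse-function
  rule R'' = -f'' / f'**3.  Positive curvature at the origin means sigmoidal.
* **sign change** - the exact second derivative evaluated along a uniform
  200-point signal grid; sigmoidal iff it switches from positive to negative
  (runs of at least two consecutive points of each sign, to guard against
  isolated numerical flips).

Necessary conditions for sigmoidality in the simple monofunctional model:
(i) k_h1 > 0, (ii) k_2 > k_2r, and (iii) k_3r > k_3 or k_3r + k_4r >
k_3 + k_4; in addition k_3r must be non-zero.  Violating any of them forces
a hyperbolic curve, which the survey machinery asserts empirically.

The Hill coefficient n_H = log(81) / log(input90/input10) summarizes curve
steepness: 1 for a Michaelis-Menten curve, >1 for ultrasensitive responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._jet import Jet
from .core_model import ParameterSet, Topology, bind_parameters
from .steady_state import (
    SignalResponseCurve,
    build_curve,
    eliminate,
    is_responsive,
    maximal_response,
    NonResponsiveTopology,
    signal_for_response,
    signal_for_response_grid,
)

__all__ = [
    "IndeterminateCurvature",
    "ClassificationResult",
    "f_derivatives",
    "curvature_at_zero",
    "classify",
    "sign_change_along_curve",
    "necessary_conditions",
    "hill_coefficient",
]

HYPERBOLIC = "hyperbolic"
SIGMOIDAL = "sigmoidal"


class IndeterminateCurvature(ValueError):
    """f'(0) vanished; the curvature of the inverse curve is undefined."""


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    curvature_sign_at_zero: int
    sign_change_detected: bool | None
    hill_coefficient: float
    method: str


def f_derivatives(rr0, topology: Topology, params: ParameterSet,
                  kh0: float = 0.0, kh3: float = 0.0):
    """Exact ``(f, f', f'')`` of the signal function at response level rr0.

    Computed by propagating a second-order jet through the rational
    elimination formulas, so the values are accurate to machine precision.
    Accepts scalar or array ``rr0``.
    """
    p = bind_parameters(topology, params)
    jet = Jet.variable(np.asarray(rr0, dtype=float) if np.ndim(rr0) else float(rr0))
    *_, ks = eliminate(jet, p, kh0, kh3)
    return ks.f, ks.d1, ks.d2


def curvature_at_zero(topology: Topology, params: ParameterSet,
                      kh0: float = 0.0, kh3: float = 0.0) -> float:
    """Second derivative of the response curve RR~P(ks) at ks = 0.

    By the inverse-function rule this is ``-f''(0) / f'(0)**3``; a positive
    value marks a sigmoidal (initially convex) signal-response relationship.
    """
    if kh0 == 0.0 and kh3 == 0.0 and not is_responsive(topology):
        raise NonResponsiveTopology(f"{topology} has no signal-response curve")
    f0, f1, f2 = f_derivatives(0.0, topology, params, kh0, kh3)
    if not (f1 > 0.0) or not math.isfinite(f1):
        raise IndeterminateCurvature(
            f"f'(0) = {f1}; curve has a degenerate flat start for {topology}"
        )
    return -f2 / f1 ** 3


def inverse_curvature_grid(rr, topology: Topology, params: ParameterSet,
                           kh0: float = 0.0, kh3: float = 0.0) -> np.ndarray:
    """d2(RR~P)/dks2 evaluated at the curve points with response ``rr``."""
    f0, f1, f2 = f_derivatives(np.asarray(rr, dtype=float), topology, params,
                               kh0, kh3)
    return -f2 / f1 ** 3


def sign_change_along_curve(topology: Topology, params: ParameterSet,
                            alpha: float | None = None, n_grid: int = 200,
                            min_run: int = 2) -> bool:
    """Classification by sign change of the curvature along the whole curve.

    The second derivative of the response curve is evaluated at ``n_grid``
    points along the curve's sampling grid (uniform in response between 0
    and 0.95*alpha, matching the curve-construction convention; a
    signal-uniform grid under-resolves narrow convex onsets); the curve is
    sigmoidal iff a run of >= ``min_run`` positive values is followed by a
    run of >= ``min_run`` negative values.
    """
    p = bind_parameters(topology, params)
    if alpha is None:
        alpha = maximal_response(topology, p)
    rr_pts = np.linspace(0.0, 0.95 * alpha, n_grid + 1)[1:]
    curv = inverse_curvature_grid(rr_pts, topology, p)
    return _pos_to_neg_run(np.sign(curv), min_run)


def _pos_to_neg_run(signs: np.ndarray, min_run: int) -> bool:
    run_val, run_len, seen_pos = 0.0, 0, False
    for s in signs:
        if s == run_val:
            run_len += 1
        else:
            run_val, run_len = s, 1
        if run_val > 0 and run_len >= min_run:
            seen_pos = True
        if seen_pos and run_val < 0 and run_len >= min_run:
            return True
    return False


def necessary_conditions(params: ParameterSet) -> tuple[bool, dict[str, bool]]:
    """The analytic necessary conditions for a sigmoidal response.

    Sigmoidality requires (i) hydrolysis of REC~P (``k_h1 > 0``), (ii)
    forward-dominant exchange between HK and REC (``k_2 > k_2r``), and (iii)
    reverse dominance at the lower layers: ``k_3r > k_3`` or ``k_3r * k_4r >
    k_3 * k_4``.  The product form of (iii) is the contrapositive of the
    curvature-sign implication (a curve is hyperbolic whenever ``k_3 > k_3r``
    and ``k_3 k_4 > k_3r k_4r``); with either clause, ``k_3r > 0`` is forced
    and is reported separately.  All inequalities are strict.

    Returns the overall verdict and a per-condition breakdown.
    """
    p = params
    breakdown = {
        "rec_hydrolysis": p.k_h1 > 0.0,
        "forward_dominant_hk_rec": p.k_2 > p.k_2r,
        "reverse_dominant_lower_layers": (p.k_3r > p.k_3)
        or (p.k_3r * p.k_4r > p.k_3 * p.k_4),
        "rec_hpt_reverse_present": p.k_3r > 0.0,
    }
    return all(breakdown.values()), breakdown


def hill_coefficient(curve: SignalResponseCurve) -> float:
    """Steepness summary n_H = log(81) / log(input90 / input10).

    ``input10`` and ``input90`` are the signals generating 10% and 90% of the
    maximal response alpha, obtained by monotone (PCHIP) interpolation of the
    sampled curve.  Returns NaN when the grid does not reach 90% of alpha.
    """
    rr, ks, alpha = curve.rr_grid, curve.ks_values, curve.alpha
    if rr[-1] < 0.9 * alpha:
        return float("nan")
    interp = PchipInterpolator(rr, ks)
    s10 = float(interp(0.1 * alpha))
    s90 = float(interp(0.9 * alpha))
    if not (s90 > s10 > 0.0):
        return float("nan")
    return math.log(81.0) / math.log(s90 / s10)


def _hill_from_f(topology, params, alpha) -> float:
    """n_H by direct evaluation of f at 10% and 90% of alpha (no interpolation)."""
    s10 = signal_for_response(0.1 * alpha, topology, params)
    s90 = signal_for_response(0.9 * alpha, topology, params)
    if not (s90 > s10 > 0.0):
        return float("nan")
    return math.log(81.0) / math.log(s90 / s10)


def classify_curve_data(ks, rr, method: str = "curvature_at_zero",
                        min_run: int = 2) -> ClassificationResult:
    """Classify a curve given only sampled ``(ks, rr)`` data.

    Used for synthetic/analytic reference curves and as a fallback when no
    model provenance is attached.  The second derivative of response with
    respect to signal is estimated by repeated numerical differentiation on
    the (possibly non-uniform) grid.
    """
    ks = np.asarray(ks, dtype=float)
    rr = np.asarray(rr, dtype=float)
    d1 = np.gradient(rr, ks)
    d2 = np.gradient(d1, ks)
    # skip the one-sided endpoint estimate when judging curvature at zero
    curv0 = d2[1] if len(d2) > 2 else d2[0]
    sign0 = int(np.sign(curv0))
    sign_change = _pos_to_neg_run(np.sign(d2[1:-1]), min_run)
    if method == "curvature_at_zero":
        label = SIGMOIDAL if sign0 > 0 else HYPERBOLIC
    elif method == "sign_change":
        label = SIGMOIDAL if sign_change else HYPERBOLIC
    else:
        raise ValueError(f"unknown classification method {method!r}")
    return ClassificationResult(label, sign0, sign_change, float("nan"), method)


def classify(target, params: ParameterSet | None = None,
             method: str = "curvature_at_zero",
             with_hill: bool = True) -> ClassificationResult:
    """Classify a signal-response relationship as hyperbolic or sigmoidal.

    ``target`` is either a :class:`SignalResponseCurve` or a topology (with
    ``params`` supplied).  ``method`` selects the curvature-at-zero test
    (default) or the whole-curve sign-change test; the curvature sign at zero
    is reported either way.
    """
    if isinstance(target, SignalResponseCurve):
        if target.topology is None:
            return classify_curve_data(target.ks_values, target.rr_grid, method)
        topology, p, alpha = target.topology, target.params, target.alpha
    else:
        if params is None:
            raise TypeError("params are required when target is a Topology")
        topology, p = target, bind_parameters(target, params)
        alpha = None

    curv0 = curvature_at_zero(topology, p)
    sign0 = int(np.sign(curv0))
    sign_change = None
    if method == "curvature_at_zero":
        label = SIGMOIDAL if sign0 > 0 else HYPERBOLIC
    elif method == "sign_change":
        if alpha is None:
            alpha = maximal_response(topology, p)
        sign_change = sign_change_along_curve(topology, p, alpha=alpha)
        label = SIGMOIDAL if sign_change else HYPERBOLIC
    else:
        raise ValueError(f"unknown classification method {method!r}")

    nh = float("nan")
    if with_hill:
        if alpha is None:
            alpha = maximal_response(topology, p)
        nh = _hill_from_f(topology, p, alpha)
    return ClassificationResult(label, sign0, sign_change, nh, method)
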