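"""Step-response timing of the relay.

The response time is the time taken for phosphorylated RR to settle at its
new steady state after a 10% step in the signal ``k_s``, starting from the
exact steady state at a basal signal.  The basal signal is defined through
the response level: for a basal fraction b in {0.2, 0.5, 0.8} the basal
signal is ``k_s* = f(b * alpha)``, i.e. the signal that produces a response
of b times the maximal response.  Settling is detected when RR~P enters and
stays within a band of 1% of the net response change around the new steady
state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_model import ParameterSet, Topology, bind_parameters, ode_rhs
from .steady_state import (
    invert_signal,
    maximal_response,
    signal_for_response,
    steady_state_from_response,
)

__all__ = ["ResponseTimeResult", "response_time"]


@dataclass(frozen=True)
class ResponseTimeResult:
    basal_fraction: float
    direction: str
    basal_signal: float
    stepped_signal: float
    initial_response: float
    final_response: float
    time: float
    regime: str | None = None


def response_time(topology: Topology, params: ParameterSet,
                  basal_fraction: float = 0.5, direction: str = "up",
                  rel_step: float = 0.10, band_fraction: float = 0.01,
                  regime: str | None = None,
                  n_eval: int = 4000) -> ResponseTimeResult:
    """Switch-on (or switch-off) time after a ±``rel_step`` signal step.

    The system starts at the exact steady state for the basal signal
    ``f(basal_fraction * alpha)``; the signal is stepped up or down by
    ``rel_step`` and the stiff ODE integrated until RR~P settles.  The
    reported time is the first time after which RR~P remains within
    ``band_fraction`` of the net change around the new steady state.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    p = bind_parameters(topology, params)
    alpha = maximal_response(topology, p)
    rr0 = basal_fraction * alpha
    ks0 = signal_for_response(rr0, topology, p)
    factor = 1.0 + rel_step if direction == "up" else 1.0 - rel_step
    ks1 = ks0 * factor
    if ks1 == ks0:
        return ResponseTimeResult(basal_fraction, direction, ks0, ks1,
                                  rr0, rr0, 0.0, regime)
    rr1 = invert_signal(ks1, topology, p, alpha=alpha)
    net = rr1 - rr0
    band = band_fraction * abs(net)
    if band == 0.0:
        raise ValueError("signal step produced no net response change")

    y0 = steady_state_from_response(topology, p, rr0)
    p1 = dc_replace(p, k_s=ks1)
    scale = max(p1.totals)

    def rhs(t, y):
        return ode_rhs(t, y, p1)

    # expand the horizon until the trajectory has settled into the band
    t_end = 10.0 / ks1 if ks1 > 0 else 10.0
    y = y0
    t_off = 0.0
    segments = []
    n_steps = 0
    for _ in range(60):
        sol = solve_ivp(rhs, (0.0, t_end), y, method="LSODA",
                        rtol=1e-9, atol=1e-12 * scale, dense_output=True)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(sol.message)
        n_steps += len(sol.t)
        if n_steps > 300_000:
            raise RuntimeError(
                "step-response integration pathologically stiff "
                f"(> {n_steps} steps)"
            )
        segments.append((t_off, t_end, sol.sol))
        y_end = sol.y[:, -1]
        settled = (abs(y_end[7] - rr1) < band
                   and np.max(np.abs(rhs(0.0, y_end))) < 1e-9 * scale)
        if settled:
            break
        y = y_end
        t_off += t_end
        t_end *= 2.0
    else:  # pragma: no cover
        raise RuntimeError("trajectory did not settle within the horizon")

    total_t = t_off + t_end
    ts = np.linspace(0.0, total_t, n_eval)
    rrp = np.empty_like(ts)
    for off, length, interp in segments:
        m = (ts >= off) & (ts <= off + length)
        rrp[m] = interp(ts[m] - off)[7]
    def rrp_at(t):
        for off, length, interp in segments:
            if off <= t <= off + length:
                return float(interp(t - off)[7])
        return float(segments[-1][2](segments[-1][1])[7])  # pragma: no cover

    outside = np.abs(rrp - rr1) > band
    if not outside.any():
        t_resp = 0.0
    else:
        last = np.flatnonzero(outside)[-1]
        if last + 1 >= len(ts):
            t_resp = float(ts[-1])  # pragma: no cover - unsettled tail
        else:
            t_resp = float(brentq(
                lambda t: abs(rrp_at(t) - rr1) - band,
                ts[last], ts[last + 1], xtol=1e-12 * max(ts[last + 1], 1.0),
            ))
    return ResponseTimeResult(basal_fraction, direction, ks0, ks1,
                              rr0, rr1, t_resp, regime)
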