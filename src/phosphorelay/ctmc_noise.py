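"""Intrinsic noise of the relay at small copy number.

The simple monofunctional relay with per-layer conservation is, at small
molecule counts, a continuous-time Markov chain on the lattice of
phospho-counts ``(n_HKp, n_RECp, n_Hptp, n_RRp)`` with each count in
``0..N``.  Concentrations map to counts through the volume scaling factor
``g`` (molecules per concentration unit), chosen so each layer's total maps
to ``N`` molecules; bimolecular stochastic rates are the mass-action rate
constants divided by ``g``, unimolecular rates are unchanged.

Only stochasticity intrinsic to the reaction events is modeled; parameters
do not fluctuate.  The stationary distribution is obtained by an exact
sparse linear solve of ``pi Q = 0`` on the reachable communicating class,
with a Gillespie stochastic-simulation cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import LinearOperator, lgmres, spilu, spsolve

from .core_model import ParameterSet, Topology, bind_parameters

__all__ = [
    "StochasticConfig",
    "CTMCResult",
    "build_generator",
    "stationary_distribution",
    "stationary_noise",
    "ssa_trajectories",
]


@dataclass(frozen=True)
class StochasticConfig:
    """Copy-number scaling for the stochastic treatment.

    ``N`` molecules per layer total (default 10, i.e. 14,641 lattice states);
    ``state_cap`` guards against accidentally huge state spaces.
    """

    N: int = 10
    seed: int | None = None
    state_cap: int = 500_000

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")


def _common_total(params: ParameterSet) -> float:
    totals = np.array(params.totals)
    if np.max(np.abs(totals - totals[0])) > 1e-9 * totals[0]:
        raise ValueError(
            "stochastic analysis requires equal totals at all four layers "
            "(one scaling factor g cannot map unequal totals to N molecules)"
        )
    return float(totals[0])


def _transition_table(topology: Topology, params: ParameterSet,
                      config: StochasticConfig, ks: float):
    """Propensity coefficients and count changes for the 9 reaction channels."""
    p = bind_parameters(topology, params)
    g = config.N / _common_total(p)  # molecules per concentration unit
    # (rate, uses, delta) with `uses` a callable of count arrays
    N = config.N
    channels = [
        (ks, lambda a, b, c, d: N - a, (+1, 0, 0, 0)),
        (p.k_2 / g, lambda a, b, c, d: a * (N - b), (-1, +1, 0, 0)),
        (p.k_2r / g, lambda a, b, c, d: (N - a) * b, (+1, -1, 0, 0)),
        (p.k_3 / g, lambda a, b, c, d: b * (N - c), (0, -1, +1, 0)),
        (p.k_3r / g, lambda a, b, c, d: (N - b) * c, (0, +1, -1, 0)),
        (p.k_4 / g, lambda a, b, c, d: c * (N - d), (0, 0, -1, +1)),
        (p.k_4r / g, lambda a, b, c, d: (N - c) * d, (0, 0, +1, -1)),
        (p.k_h1, lambda a, b, c, d: b, (0, -1, 0, 0)),
        (p.k_h2, lambda a, b, c, d: d, (0, 0, 0, -1)),
    ]
    return channels


def build_generator(topology: Topology, params: ParameterSet,
                    config: StochasticConfig, ks: float):
    """Sparse CTMC generator Q over the phospho-count lattice.

    Returns ``(Q, counts)`` where ``counts`` is the ``(n_states, 4)`` array
    of phospho-counts per state.  Row sums of Q are zero.
    """
    N = config.N
    n_states = (N + 1) ** 4
    if n_states > config.state_cap:
        raise ValueError(
            f"state space has {n_states} states, exceeding cap {config.state_cap}"
        )
    idx = np.arange(n_states)
    d = idx % (N + 1)
    c = (idx // (N + 1)) % (N + 1)
    b = (idx // (N + 1) ** 2) % (N + 1)
    a = idx // (N + 1) ** 3
    counts = np.stack([a, b, c, d], axis=1)

    rows, cols, vals = [], [], []
    for rate, uses, (da, db, dc, dd) in _transition_table(topology, params,
                                                          config, ks):
        if rate == 0.0:
            continue
        prop = rate * uses(a, b, c, d).astype(float)
        mask = prop > 0.0
        if not np.any(mask):
            continue
        src = idx[mask]
        dst = (src + da * (N + 1) ** 3 + db * (N + 1) ** 2 + dc * (N + 1) + dd)
        rows.append(src)
        cols.append(dst)
        vals.append(prop[mask])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:  # no reactions at all (e.g. ks = 0 and empty state)
        rows = cols = np.array([], dtype=int)
        vals = np.array([])
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q, counts


def _closed_class(Q: sp.csr_matrix) -> np.ndarray:
    """Indices of the unique closed communicating class of the chain."""
    n = Q.shape[0]
    n_comp, labels = connected_components(Q, directed=True, connection="strong")
    if n_comp == 1:
        return np.arange(n)
    out_mass = np.zeros(n_comp)
    coo = Q.tocoo()
    off = labels[coo.row] != labels[coo.col]
    np.add.at(out_mass, labels[coo.row[off]], np.maximum(coo.data[off], 0.0))
    closed_comps = np.flatnonzero(out_mass <= 0.0)
    if len(closed_comps) != 1:
        raise RuntimeError(
            f"expected a unique closed communicating class, found "
            f"{len(closed_comps)}"
        )
    return np.flatnonzero(labels == closed_comps[0])


def _pinned_system(Q: sp.spmatrix, pin: int = 0):
    """Balance equations with ``pi[pin]`` fixed to 1 (keeps the matrix sparse).

    Pinning a high-probability state (e.g. the state nearest the
    deterministic steady state) conditions the system far better than
    pinning an arbitrary corner of the lattice, because the unknown ratios
    ``pi_i / pi_pin`` then stay moderate.
    """
    n = Q.shape[0]
    if pin != 0:
        order = np.concatenate([[pin], np.arange(pin),
                                np.arange(pin + 1, n)])
        A = Q.T.tocsr()[order][:, order]
    else:
        order = None
        A = Q.T.tocsr()
    B = A[1:][:, 1:].tocsc()
    rhs = -np.asarray(A[1:][:, 0].todense()).ravel()
    return B, rhs, order


def _unpin(y: np.ndarray, n: int, order) -> np.ndarray:
    vec = np.concatenate([[1.0], y])
    if order is not None:
        pi = np.empty(n)
        pi[order] = vec
    else:
        pi = vec
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def make_preconditioner(Q: sp.spmatrix, pin: int = 0, drop_tol: float = 1e-4,
                        fill_factor: int = 15) -> LinearOperator:
    """Incomplete-LU preconditioner for the pinned balance system of Q."""
    B, _, _ = _pinned_system(Q, pin)
    ilu = spilu(B, drop_tol=drop_tol, fill_factor=fill_factor)
    return LinearOperator(B.shape, ilu.solve)


def _power_stationary(Q, tol=1e-10, max_iter=500_000, check_every=50):
    """Uniformization power iteration; robust fallback for any size."""
    n = Q.shape[0]
    lam = float(-Q.diagonal().min()) * 1.0001
    if lam <= 0:
        return np.full(n, 1.0 / n)
    PT = (sp.identity(n, format="csr") + Q.tocsr() / lam).T.tocsr()
    QT = Q.T.tocsr()
    pi = np.full(n, 1.0 / n)
    for i in range(max_iter):
        pi = PT @ pi
        if i % check_every == 0:
            pi /= pi.sum()
            if np.abs(QT @ pi).sum() / lam < tol:
                break
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_distribution(Q: sp.csr_matrix, method: str = "auto",
                            pin_state: int = 0,
                            preconditioner: LinearOperator | None = None,
                            ) -> np.ndarray:
    """Stationary distribution of Q on its closed communicating class.

    States outside the closed class get probability zero.  ``method`` is
    ``"direct"`` (sparse LU), ``"ilu"`` (ILU-preconditioned LGMRES, the
    default for large lattices), ``"power"`` (uniformization iteration) or
    ``"auto"``.  ``pin_state`` selects the state whose balance equation is
    replaced by the normalization; pinning a high-probability state keeps
    the system well conditioned.  A ``preconditioner`` built by
    :func:`make_preconditioner` with the same pin may be supplied to
    amortize the ILU cost across a signal grid.
    """
    n = Q.shape[0]
    members = _closed_class(Q)
    restricted = len(members) < n
    Qc = Q[members][:, members] if restricted else Q
    m = len(members)
    if m == 1:
        pi_c = np.array([1.0])
    else:
        pin = pin_state
        if restricted:
            where = np.flatnonzero(members == pin_state)
            pin = int(where[0]) if len(where) else 0
        if method == "auto":
            method = "direct" if m <= 5000 else "ilu"
        if method == "power":
            pi_c = _power_stationary(Qc)
        else:
            B, rhs, order = _pinned_system(Qc, pin)
            if method == "direct":
                y = spsolve(B, rhs)
            elif method == "ilu":
                M = preconditioner
                if M is None or M.shape != B.shape:
                    M = make_preconditioner(Qc, pin)
                y, info = lgmres(B, rhs, M=M, rtol=1e-12, atol=0.0,
                                 maxiter=200)
                if info != 0:
                    # stale preconditioner (e.g. reused across a wide signal
                    # grid): refactorize for this generator and retry
                    M = make_preconditioner(Qc, pin)
                    y, info = lgmres(B, rhs, M=M, rtol=1e-12, atol=0.0,
                                     maxiter=1000)
                    if info != 0:  # pragma: no cover - last resort
                        y = spsolve(B, rhs)
            else:
                raise ValueError(f"unknown method {method!r}")
            pi_c = _unpin(y, m, order)
    pi_c = np.clip(pi_c, 0.0, None)
    pi_c /= pi_c.sum()
    if not restricted:
        return pi_c
    pi = np.zeros(n)
    pi[members] = pi_c
    return pi


@dataclass(frozen=True)
class CTMCResult:
    """Stationary moments of the phospho-RR fraction along a signal grid."""

    signal_grid: np.ndarray
    mean_fraction: np.ndarray
    sd_fraction: np.ndarray

    @property
    def noise(self) -> np.ndarray:
        """Coefficient of variation SD/mean (NaN where the mean vanishes)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mean_fraction > 0,
                            self.sd_fraction / self.mean_fraction, np.nan)


def stationary_noise(topology: Topology, params: ParameterSet,
                     config: StochasticConfig, signal_grid) -> CTMCResult:
    """Exact stationary mean, SD and CV of the RR~P fraction per signal."""
    signal_grid = np.asarray(signal_grid, dtype=float)
    means, sds = [], []
    for ks in signal_grid:
        Q, counts = build_generator(topology, params, config, ks)
        pin = _deterministic_pin(topology, params, config, float(ks))
        pi = stationary_distribution(Q, pin_state=pin)
        frac = counts[:, 3] / config.N
        mean = float(pi @ frac)
        var = float(pi @ frac ** 2) - mean ** 2
        means.append(mean)
        sds.append(np.sqrt(max(var, 0.0)))
    return CTMCResult(signal_grid, np.array(means), np.array(sds))


def _deterministic_pin(topology: Topology, params: ParameterSet,
                       config: StochasticConfig, ks: float) -> int:
    """Lattice state nearest the deterministic steady state at signal *ks*.

    Used as the pinned state of the balance solve; falls back to the empty
    state when the deterministic fixed point is unavailable.
    """
    from .steady_state import eliminate, invert_signal, is_responsive

    if ks <= 0 or not is_responsive(topology):
        return 0
    p = bind_parameters(topology, params)
    try:
        rr = invert_signal(ks, topology, p)
        hptp, recp, hkp, _ = eliminate(rr, p)
    except Exception:
        return 0
    N = config.N
    g = N / _common_total(p)
    cnt = np.clip(np.round(np.array([hkp, recp, hptp, rr]) * g), 0, N)
    a, b, c, d = cnt.astype(int)
    return int(((a * (N + 1) + b) * (N + 1) + c) * (N + 1) + d)


def ssa_trajectories(topology: Topology, params: ParameterSet,
                     config: StochasticConfig, ks: float, t_end: float,
                     n_reps: int = 5, burn_in: float = 0.5):
    """Gillespie direct-method estimate of the stationary RR~P fraction.

    Returns ``(mean, sd, se_mean)`` of the time-averaged fraction: per-rep
    time averages past the burn-in fraction of the horizon, pooled over
    replicates.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    channels = _transition_table(topology, params, config, ks)
    N = config.N
    deltas = np.array([ch[2] for ch in channels])
    rates = np.array([ch[0] for ch in channels])

    rep_means, rep_vars = [], []
    t_burn = burn_in * t_end
    for _ in range(n_reps):
        state = np.zeros(4, dtype=int)
        t = 0.0
        acc_t = acc_d = acc_d2 = 0.0
        while t < t_end:
            a, b, c, d = state
            props = rates * np.array([ch[1](a, b, c, d) for ch in channels],
                                     dtype=float)
            total = props.sum()
            if total <= 0.0:
                dwell = t_end - max(t, t_burn)
                if dwell > 0:
                    acc_t += dwell
                    acc_d += dwell * d
                    acc_d2 += dwell * d * d
                break
            dt = rng.exponential(1.0 / total)
            t_next = min(t + dt, t_end)
            dwell = max(0.0, min(t_next, t_end) - max(t, t_burn))
            if dwell > 0:
                acc_t += dwell
                acc_d += dwell * d
                acc_d2 += dwell * d * d
            if t + dt > t_end:
                break
            j = rng.choice(len(channels), p=props / total)
            state = state + deltas[j]
            t += dt
        if acc_t > 0:
            m = acc_d / acc_t / N
            rep_means.append(m)
            rep_vars.append(acc_d2 / acc_t / N ** 2 - m ** 2)
    rep_means = np.array(rep_means)
    mean = float(rep_means.mean())
    sd = float(np.sqrt(max(np.mean(rep_vars), 0.0)))
    se = float(rep_means.std(ddof=1) / np.sqrt(len(rep_means))) \
        if len(rep_means) > 1 else float("nan")
    return mean, sd, se
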