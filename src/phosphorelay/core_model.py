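"""Reaction network of the generic four-layered phosphorelay.

The relay transfers phosphoryl groups along HK -> REC -> Hpt -> RR.  The
sensor histidine kinase (HK) autophosphorylates at rate ``k_s`` (the signal
proxy); forward phosphotransfer proceeds with bimolecular rate constants
``k_2`` (HK~P + REC), ``k_3`` (REC~P + Hpt) and ``k_4`` (Hpt~P + RR), and each
transfer may run in reverse (``k_2r``, ``k_3r``, ``k_4r``).  Phospho-aspartate
residues on REC and RR are hydrolysis-prone (first-order rates ``k_h1``,
``k_h2``).  A topology is the subset of the three reverse-transfer and two
hydrolysis reactions that are present; there are 2**5 = 32 of them.

Units are dimensionless but coherent: concentrations in one arbitrary unit,
time in another; bimolecular rate constants carry conc^-1 time^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "Topology",
    "ParameterSet",
    "SPECIES",
    "enumerate_topologies",
    "topology_by_id",
    "topology_by_code",
    "bind_parameters",
    "ode_rhs",
    "initial_state",
    "state_from_phospho",
    "conservation_residual",
]

# Within each hydrolysis block the reverse-transfer codes appear in this
# order; blocks are ordered by hydrolysis code.  The assignment is the unique
# one consistent with every reference id <-> code pair for the responsive
# topologies (checked at import time below).
_REV_ORDER = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 0, 1),
    (1, 1, 0),
    (0, 1, 1),
    (0, 0, 0),
    (1, 1, 1),
)
_HYD_ORDER = ((0, 1), (1, 0), (0, 0), (1, 1))

#: Species ordering of the simple (monofunctional) model state vector.
SPECIES = ("HK", "HKp", "REC", "RECp", "Hpt", "Hptp", "RR", "RRp")


@dataclass(frozen=True)
class Topology:
    """One of the 32 four-layered relay topologies.

    ``r2``/``r3``/``r4`` flag the reverse phosphotransfer reactions
    HK<-REC, REC<-Hpt and Hpt<-RR; ``h1``/``h2`` flag hydrolysis of REC~P
    and RR~P.
    """

    id: int
    r2: bool
    r3: bool
    r4: bool
    h1: bool
    h2: bool

    @property
    def rev_flags(self) -> tuple[bool, bool, bool]:
        return (self.r2, self.r3, self.r4)

    @property
    def hyd_flags(self) -> tuple[bool, bool]:
        return (self.h1, self.h2)

    @property
    def code(self) -> str:
        """Five-digit binary identification code ``r2 r3 r4 h1 h2``."""
        bits = (self.r2, self.r3, self.r4, self.h1, self.h2)
        return " ".join("1" if b else "0" for b in bits)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"topology {self.id} [{self.code}]"


def enumerate_topologies() -> list[Topology]:
    """Return the 32 topologies, ordered by identification number 1..32."""
    out = []
    tid = 0
    for h1, h2 in _HYD_ORDER:
        for r2, r3, r4 in _REV_ORDER:
            tid += 1
            out.append(Topology(tid, bool(r2), bool(r3), bool(r4), bool(h1), bool(h2)))
    return out


_ALL = enumerate_topologies()
_BY_ID = {t.id: t for t in _ALL}
_BY_FLAGS = {(t.rev_flags, t.hyd_flags): t for t in _ALL}


def topology_by_id(tid: int) -> Topology:
    try:
        return _BY_ID[tid]
    except KeyError:
        raise ValueError(f"topology id must be in 1..32, got {tid!r}") from None


def topology_by_code(rev: tuple[int, int, int], hyd: tuple[int, int]) -> Topology:
    key = (tuple(bool(b) for b in rev), tuple(bool(b) for b in hyd))
    return _BY_FLAGS[key]


# reference id <-> code pairs for the 18 responsive topologies; the
# enumeration must reproduce every one of them.
_REFERENCE_CODES = {
    1: (1, 0, 0, 0, 1), 2: (0, 1, 0, 0, 1), 3: (0, 0, 1, 0, 1),
    4: (1, 0, 1, 0, 1), 5: (1, 1, 0, 0, 1), 6: (0, 1, 1, 0, 1),
    7: (0, 0, 0, 0, 1), 8: (1, 1, 1, 0, 1), 14: (0, 1, 1, 1, 0),
    16: (1, 1, 1, 1, 0), 25: (1, 0, 0, 1, 1), 26: (0, 1, 0, 1, 1),
    27: (0, 0, 1, 1, 1), 28: (1, 0, 1, 1, 1), 29: (1, 1, 0, 1, 1),
    30: (0, 1, 1, 1, 1), 31: (0, 0, 0, 1, 1), 32: (1, 1, 1, 1, 1),
}
for _tid, _bits in _REFERENCE_CODES.items():
    _t = _BY_ID[_tid]
    assert (_t.r2, _t.r3, _t.r4, _t.h1, _t.h2) == tuple(map(bool, _bits)), (
        f"topology enumeration inconsistent with reference code for id {_tid}"
    )
del _tid, _bits, _t


#: Rate-constant and total-concentration fields in the canonical column order
#: (k_2 .. k_6 then the four totals); k_s is the signal and comes separately.
PARAM_ORDER = (
    "k_2", "k_3", "k_4", "k_2r", "k_3r", "k_4r", "k_h1", "k_h2",
    "k_5", "k_5r", "k_6", "HK_tot", "REC_tot", "Hpt_tot", "RR_tot",
)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and total concentrations for one relay instance.

    ``k_5``, ``k_5r`` and ``k_6`` (bifunctional-HK binding, unbinding and
    catalytic dephosphorylation) are only used by the bifunctional variant and
    default to zero.  ``k_s`` is the signal (HK autophosphorylation rate) and
    defaults to zero; it is the independent variable of the signal-response
    analysis.
    """

    k_2: float
    k_3: float
    k_4: float
    k_2r: float = 0.0
    k_3r: float = 0.0
    k_4r: float = 0.0
    k_h1: float = 0.0
    k_h2: float = 0.0
    k_5: float = 0.0
    k_5r: float = 0.0
    k_6: float = 0.0
    HK_tot: float = 1.0
    REC_tot: float = 1.0
    Hpt_tot: float = 1.0
    RR_tot: float = 1.0
    k_s: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        for name in ("k_2", "k_3", "k_4", "HK_tot", "REC_tot", "Hpt_tot", "RR_tot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def totals(self) -> tuple[float, float, float, float]:
        return (self.HK_tot, self.REC_tot, self.Hpt_tot, self.RR_tot)

    def as_row(self) -> list[float]:
        """The 15 values in canonical column order (without ``k_s``)."""
        return [getattr(self, n) for n in PARAM_ORDER]

    @classmethod
    def from_row(cls, row, k_s: float = 0.0) -> "ParameterSet":
        vals = [float(x) for x in row]
        if len(vals) != len(PARAM_ORDER):
            raise ValueError(f"expected {len(PARAM_ORDER)} values, got {len(vals)}")
        return cls(**dict(zip(PARAM_ORDER, vals)), k_s=k_s)


def bind_parameters(topology: Topology, params: ParameterSet) -> ParameterSet:
    """Zero out the rate constants of reactions absent from *topology*.

    Raises ``ValueError`` if a rate the topology requires (a forward rate, or
    a flagged reverse/hydrolysis rate) is zero: such an instance is degenerate
    and effectively belongs to a different topology.
    """
    required = {"k_2": True, "k_3": True, "k_4": True,
                "k_2r": topology.r2, "k_3r": topology.r3, "k_4r": topology.r4,
                "k_h1": topology.h1, "k_h2": topology.h2}
    updates = {}
    for name, present in required.items():
        v = getattr(params, name)
        if present and v == 0.0:
            raise ValueError(
                f"{name} is required by {topology} but is zero (degenerate instance)"
            )
        if not present and v != 0.0:
            updates[name] = 0.0
    return replace(params, **updates) if updates else params


def ode_rhs(t, y, params: ParameterSet):
    """Mass-action right-hand side of the simple (monofunctional) model.

    State ordering follows :data:`SPECIES`.  The signal is ``params.k_s``.
    Derivatives sum to zero within each layer's conservation class.
    """
    HK, HKp, REC, RECp, Hpt, Hptp, RR, RRp = y
    p = params
    auto = p.k_s * HK
    j2 = p.k_2 * HKp * REC - p.k_2r * HK * RECp
    j3 = p.k_3 * RECp * Hpt - p.k_3r * REC * Hptp
    j4 = p.k_4 * Hptp * RR - p.k_4r * RRp * Hpt
    h1 = p.k_h1 * RECp
    h2 = p.k_h2 * RRp
    return np.array([
        -auto + j2,          # HK
        auto - j2,           # HK~P
        -j2 + j3 + h1,       # REC
        j2 - j3 - h1,        # REC~P
        -j3 + j4,            # Hpt
        j3 - j4,             # Hpt~P
        -j4 + h2,            # RR
        j4 - h2,             # RR~P
    ])


def initial_state(params: ParameterSet) -> np.ndarray:
    """Fully unphosphorylated state at the given totals."""
    return np.array([params.HK_tot, 0.0, params.REC_tot, 0.0,
                     params.Hpt_tot, 0.0, params.RR_tot, 0.0])


def state_from_phospho(params: ParameterSet, HKp: float, RECp: float,
                       Hptp: float, RRp: float) -> np.ndarray:
    """Full state vector from the four phosphorylated concentrations."""
    return np.array([
        params.HK_tot - HKp, HKp,
        params.REC_tot - RECp, RECp,
        params.Hpt_tot - Hptp, Hptp,
        params.RR_tot - RRp, RRp,
    ])


def conservation_residual(y, params: ParameterSet) -> float:
    """Largest relative drift of the four per-layer totals."""
    y = np.asarray(y)
    tot = np.array(params.totals)
    layer = y[0::2] + y[1::2]
    return float(np.max(np.abs(layer - tot) / tot))
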