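"""Seeded parameter sampling and topology-wide classification surveys.

The sampler emulates drawing relay instances from a broad, biologically
permissible regime: bimolecular phosphotransfer rate constants log-uniform
over [1e-2, 1e2] (forward and reverse drawn independently and identically,
so ratio-based sigmoidality conditions are scale-free), hydrolysis rates
log-uniform over [1e-3, 1e1], and total concentrations log-uniform over
[1e-1, 1e1], either one shared total for all four layers (``equal``) or four
independent totals (``free``).  The survey classifies 1000 sampled sets per
topology by default and reports the percentage of sigmoidal curves together
with forward/reverse rate-ratio summaries split by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import (
    HYPERBOLIC,
    SIGMOIDAL,
    IndeterminateCurvature,
    classify,
)
from .core_model import ParameterSet, Topology
from .steady_state import InfeasibleResponse, NonResponsiveTopology, is_responsive

__all__ = ["SamplingScheme", "SurveyRow", "sample_parameters", "survey",
           "survey_dataframe", "ratio_summary"]

_DEFAULT_RANGES = {
    "bimolecular": (1e-2, 1e2),
    "hydrolysis": (1e-3, 1e1),
    "totals": (1e-1, 1e1),
}

_BIMOLECULAR = ("k_2", "k_3", "k_4", "k_2r", "k_3r", "k_4r")
_HYDROLYSIS = ("k_h1", "k_h2")
_TOTALS = ("HK_tot", "REC_tot", "Hpt_tot", "RR_tot")


@dataclass(frozen=True)
class SamplingScheme:
    """Ranges and mode for one sampling campaign.

    ``ranges`` maps the three parameter groups (``bimolecular``,
    ``hydrolysis``, ``totals``) to (low, high) bounds; draws are log-uniform.
    ``totals_mode`` is ``"equal"`` (one shared total, the survey-table
    convention) or ``"free"`` (four independent totals).
    """

    n_sets: int = 1000
    seed: int = 0
    totals_mode: str = "equal"
    ranges: dict = field(default_factory=lambda: dict(_DEFAULT_RANGES))

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.totals_mode not in ("equal", "free"):
            raise ValueError("totals_mode must be 'equal' or 'free'")
        for key, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid range for {key}: ({lo}, {hi})")


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def sample_parameters(scheme: SamplingScheme, topology: Topology,
                      rng: np.random.Generator | None = None) -> list[ParameterSet]:
    """Draw ``scheme.n_sets`` parameter sets bound to *topology*.

    Deterministic given the scheme seed.  All eight rate constants are drawn
    before the topology's absent reactions are zeroed, so draws stay aligned
    across topologies under a common seed.
    """
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    r = scheme.ranges
    out = []
    present = {"k_2": True, "k_3": True, "k_4": True,
               "k_2r": topology.r2, "k_3r": topology.r3, "k_4r": topology.r4,
               "k_h1": topology.h1, "k_h2": topology.h2}
    for _ in range(scheme.n_sets):
        vals = {}
        for name in _BIMOLECULAR:
            vals[name] = float(_log_uniform(rng, *r["bimolecular"]))
        for name in _HYDROLYSIS:
            vals[name] = float(_log_uniform(rng, *r["hydrolysis"]))
        if scheme.totals_mode == "equal":
            tot = float(_log_uniform(rng, *r["totals"]))
            totals = {name: tot for name in _TOTALS}
        else:
            totals = {name: float(_log_uniform(rng, *r["totals"]))
                      for name in _TOTALS}
        for name, keep in present.items():
            if not keep:
                vals[name] = 0.0
        out.append(ParameterSet(**vals, **totals))
    return out


@dataclass(frozen=True)
class SurveyRow:
    """Per-topology survey summary (survey-table shape)."""

    topology_id: int
    code: str
    n_sets: int
    n_classified: int
    n_failed: int
    n_sigmoidal: int
    pct_sigmoidal: float
    method: str
    totals_mode: str
    seed: int
    ratio_stats: dict

    @property
    def pct_hyperbolic(self) -> float:
        return 100.0 - self.pct_sigmoidal


def ratio_summary(sets: list[ParameterSet], labels: list[str]) -> dict:
    """Mean/min/max of k_3/k_3r and k_4/k_4r split by curve label.

    Ratios are only defined when the reverse rate is present; topologies
    without the corresponding reverse reaction yield NaN entries.
    """
    stats: dict = {}
    for num, den, tag in (("k_3", "k_3r", "k3_over_k3r"),
                          ("k_4", "k_4r", "k4_over_k4r")):
        for label in (HYPERBOLIC, SIGMOIDAL):
            vals = [getattr(p, num) / getattr(p, den)
                    for p, lab in zip(sets, labels)
                    if lab == label and getattr(p, den) > 0]
            key = f"{tag}_{label}"
            if vals:
                arr = np.asarray(vals)
                stats[key] = {"mean": float(arr.mean()),
                              "median": float(np.median(arr)),
                              "gmean": float(np.exp(np.mean(np.log(arr)))),
                              "min": float(arr.min()),
                              "max": float(arr.max()),
                              "n": len(vals)}
            else:
                stats[key] = {k: float("nan") for k in
                              ("mean", "median", "gmean", "min", "max")}
                stats[key]["n"] = 0
    return stats


def survey(topologies, scheme: SamplingScheme,
           method: str = "curvature_at_zero",
           collect_details: bool = False):
    """Classify sampled parameter sets for each topology.

    Returns a list of :class:`SurveyRow`; with ``collect_details`` also a
    dict of per-topology ``(sets, labels)`` for downstream regime analysis.
    Classification failures (degenerate or infeasible instances) are counted
    and excluded from the percentage.
    """
    rows = []
    details = {}
    for top in topologies:
        if not is_responsive(top):
            raise NonResponsiveTopology(
                f"{top} is non-responsive and has no signal-response curve"
            )
        sets = sample_parameters(scheme, top)
        labels = []
        n_failed = 0
        for p in sets:
            try:
                res = classify(top, p, method=method, with_hill=False)
                labels.append(res.label)
            except (IndeterminateCurvature, InfeasibleResponse, ValueError):
                labels.append(None)
                n_failed += 1
        good = [lab for lab in labels if lab is not None]
        n_sig = sum(1 for lab in good if lab == SIGMOIDAL)
        pct = 100.0 * n_sig / len(good) if good else float("nan")
        rows.append(SurveyRow(
            topology_id=top.id, code=top.code, n_sets=scheme.n_sets,
            n_classified=len(good), n_failed=n_failed, n_sigmoidal=n_sig,
            pct_sigmoidal=round(pct, 2), method=method,
            totals_mode=scheme.totals_mode, seed=scheme.seed,
            ratio_stats=ratio_summary(sets, labels),
        ))
        if collect_details:
            details[top.id] = (sets, labels)
    return (rows, details) if collect_details else rows


def survey_dataframe(rows: list[SurveyRow]) -> pd.DataFrame:
    """Survey-table-shaped DataFrame (one row per topology)."""
    return pd.DataFrame([
        {"id": r.topology_id, "code": r.code, "n_sets": r.n_sets,
         "n_classified": r.n_classified, "n_failed": r.n_failed,
         "pct_sigmoidal": r.pct_sigmoidal, "method": r.method,
         "totals_mode": r.totals_mode, "seed": r.seed}
        for r in rows
    ])
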