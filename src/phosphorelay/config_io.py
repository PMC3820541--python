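"""Reading parameter sets / sampling schemes and writing result artifacts.

Parameter sets come either from a flat YAML mapping whose keys are the
:class:`~phosphorelay.core_model.ParameterSet` field names, or from CSV with
the canonical 15-value column order (k_2, k_3, k_4, k_2r, k_3r, k_4r, k_h1,
k_h2, k_5, k_5r, k_6, HK_tot, REC_tot, Hpt_tot, RR_tot).  Output artifacts
are CSV with a provenance comment header or JSON with a provenance block, so
every artifact records the package version and the seed that produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .core_model import PARAM_ORDER, ParameterSet
from .param_space import SamplingScheme
from .steady_state import SignalResponseCurve


def load_parameter_set(path) -> ParameterSet:
    """Parameter set from a flat YAML mapping (field name -> value)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameters")
    unknown = set(data) - set(ParameterSet.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ParameterSet(**{k: float(v) for k, v in data.items()})


def load_parameter_sets_csv(path) -> list[ParameterSet]:
    """Parameter sets from CSV, one row per set, canonical column order.

    A header row with the canonical names is accepted but optional.
    """
    first = pd.read_csv(path, nrows=0, comment="#")
    has_header = list(first.columns[: len(PARAM_ORDER)]) == list(PARAM_ORDER)
    df = pd.read_csv(path, comment="#",
                     header=0 if has_header else None)
    out = []
    for _, row in df.iterrows():
        out.append(ParameterSet.from_row(row.iloc[: len(PARAM_ORDER)]))
    return out


def load_sampling_scheme(path) -> SamplingScheme:
    """Sampling scheme from a YAML mapping (n_sets, seed, totals_mode, ranges)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_sets", "seed", "totals_mode"):
        if key in data:
            kwargs[key] = data[key]
    if "ranges" in data:
        kwargs["ranges"] = {k: tuple(map(float, v))
                            for k, v in data["ranges"].items()}
    return SamplingScheme(**kwargs)


def provenance(seed=None, **extra) -> dict:
    prov = {"package": "phosphorelay", "version": __version__}
    if seed is not None:
        prov["seed"] = seed
    prov.update(extra)
    return prov


def _header_lines(prov: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


def write_csv(df: pd.DataFrame, path, prov: dict | None = None) -> None:
    """CSV with provenance comment lines above the header."""
    with open(path, "w") as fh:
        if prov:
            fh.write(_header_lines(prov))
        df.to_csv(fh, index=False)


def curve_to_dataframe(curve: SignalResponseCurve) -> pd.DataFrame:
    return pd.DataFrame({"rr": curve.rr_grid,
                         "fraction": curve.fraction_grid,
                         "ks": curve.ks_values})


def curve_to_csv(curve: SignalResponseCurve, path) -> None:
    prov = provenance(topology=curve.topology.id, alpha=curve.alpha)
    write_csv(curve_to_dataframe(curve), path, prov)


def curve_to_json(curve: SignalResponseCurve, path) -> None:
    payload = {
        "provenance": {
            **provenance(),
            "topology": {"id": curve.topology.id, "code": curve.topology.code},
            "params": asdict(curve.params),
        },
        "alpha": curve.alpha,
        "rr": curve.rr_grid.tolist(),
        "fraction": curve.fraction_grid.tolist(),
        "ks": curve.ks_values.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
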