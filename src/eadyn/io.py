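"""Result serialization: tidy CSV tables and JSON documents.

Column order is deterministic and units are embedded in the column names
(``t_ms``, ``Vm_mV``, ...).  Multipliers are serialized as ``[re, im]``
pairs.  No binary formats.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .continuation import BifurcationPoint
from .pacing_sim import BeatTrace, SteadyStateResult
from .protocols import CensusEntry, SweepRecord

__all__ = [
    "write_traces",
    "write_diagram",
    "read_diagram",
    "write_bifurcations",
    "validate_bifurcation_doc",
    "write_sweep",
    "write_census",
    "write_steady_state",
    "write_manifest",
    "config_hash",
]

_UNIT_SUFFIX = {"t": "t_ms", "Vm": "Vm_mV", "Nai": "Nai_mM", "Cai": "Cai_mM"}

#: minimal schema for the bifurcation JSON document (field name -> type)
BIFURCATION_SCHEMA = {
    "param": str,
    "param_value": float,
    "type": str,
    "critical_multiplier": list,
    "x": list,
    "localization_width": float,
}


def _unit_name(col: str) -> str:
    return _UNIT_SUFFIX.get(col, col)


def write_traces(traces: list[BeatTrace], path) -> Path:
    """Tidy per-sample CSV: beat_index, t_ms, then state columns."""
    path = Path(path)
    frames = [tr.to_frame() for tr in traces]
    df = pd.concat(frames, ignore_index=True)
    df.columns = [_unit_name(c) for c in df.columns]
    df.to_csv(path, index=False)
    return path


def write_sweep(records: list[SweepRecord], state_names, path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "param_value": r.param_value,
            "direction": r.direction,
            "converged": r.converged,
            "period": r.period,
            "beats_used": r.beats_used,
            "response_class": r.response_class,
        }
        if r.features is not None:
            row.update(
                apd90_ms=r.features.apd90,
                n_tdmp=r.features.n_tdmp,
                dia_Nai_mM=r.features.dia_nai,
                dia_Cai_mM=r.features.dia_cai,
                peak_Cai_mM=r.features.peak_cai,
                di_ms=r.features.di,
            )
        for name, v in zip(state_names, r.state):
            row[_unit_name(name)] = float(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_diagram(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    if "bifurcations" in df.attrs:
        write_bifurcations_list(df.attrs["bifurcations"],
                                path.with_suffix(".bifurcations.json"))
    return path


def read_diagram(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bifurcations(bif_points: list[BifurcationPoint], path) -> Path:
    return write_bifurcations_list([bp.to_dict() for bp in bif_points], path)


def write_bifurcations_list(dicts: list[dict], path) -> Path:
    path = Path(path)
    doc = {"bifurcations": dicts}
    validate_bifurcation_doc(doc)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def validate_bifurcation_doc(doc: dict) -> None:
    """Check a bifurcation JSON document against the shipped schema."""
    if set(doc) != {"bifurcations"}:
        raise ValueError("document must contain exactly the 'bifurcations' key")
    for entry in doc["bifurcations"]:
        for key, typ in BIFURCATION_SCHEMA.items():
            if key not in entry:
                raise ValueError(f"bifurcation entry missing field {key!r}")
            if typ is float:
                if not isinstance(entry[key], (int, float)):
                    raise ValueError(f"field {key!r} must be numeric")
            elif not isinstance(entry[key], typ):
                raise ValueError(f"field {key!r} must be {typ.__name__}")
        if entry["type"] not in ("SN", "PD", "NS"):
            raise ValueError(f"unknown bifurcation type {entry['type']!r}")
        if len(entry["critical_multiplier"]) != 2:
            raise ValueError("critical_multiplier must be an [re, im] pair")


def write_census(entries: list[CensusEntry], state_names, path) -> Path:
    path = Path(path)
    doc = []
    for e in entries:
        doc.append(
            {
                "param_value": e.param_value,
                "order": e.order,
                "n_starts": e.n_starts,
                "n_irregular": e.n_irregular,
                "attractors": [
                    {
                        "state": {n: float(v) for n, v in zip(state_names, a.state)},
                        "period": a.period,
                        "response_class": a.response_class,
                        "n_basin_hits": a.n_basin_hits,
                    }
                    for a in e.attractors
                ],
            }
        )
    path.write_text(json.dumps({"census": doc}, indent=2, sort_keys=True))
    return path


def write_steady_state(res: SteadyStateResult, state_names, path) -> Path:
    path = Path(path)
    doc = {
        "state": {n: float(v) for n, v in zip(state_names, res.state)},
        "converged": bool(res.converged),
        "beats_used": int(res.beats_used),
        "residual": float(res.residual),
        "period": int(res.period),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


def write_manifest(path, config_text: str, wall_clock_s: float,
                   artifacts: list[str]) -> Path:
    import scipy

    from . import __version__

    path = Path(path)
    doc = {
        "config_sha256_16": config_hash(config_text),
        "versions": {
            "eadyn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "wall_clock_s": round(float(wall_clock_s), 3),
        "artifacts": sorted(artifacts),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path
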