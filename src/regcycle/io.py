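"""Configuration and table I/O.

Parameter sets and connection masks serialize to flat key-value YAML (or
JSON, which YAML subsumes); unknown keys are an error.  Tabular artefacts
(time courses, nullclines, bifurcation diagrams, screen results) are
tab-separated text with a provenance comment header, numbers written with
12 significant digits so byte-identity under a fixed seed is meaningful.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    EDGE_NAMES,
    PARAM_NAMES,
    STATE_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
)

__all__ = ["params_to_yaml", "params_from_yaml", "mask_to_yaml",
           "mask_from_yaml", "write_timecourse", "read_timecourse",
           "write_table", "FLOAT_FMT", "config_hash"]

FLOAT_FMT = "%.12g"

_POOL_KEYS = ("ulk1_total", "ampk_total")


def params_to_yaml(params: ParameterSet, path=None) -> str:
    """Flat key-value serialization of a parameter set."""
    data = {name: float(val) for name, val in params.items()}
    data.update({k: float(getattr(params, k)) for k in _POOL_KEYS})
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> ParameterSet:
    """Load a parameter set; unknown keys raise KeyError."""
    text = Path(source).read_text() if not _is_yaml_text(source) else source
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a flat mapping")
    unknown = set(data) - set(PARAM_NAMES) - set(_POOL_KEYS)
    if unknown:
        raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(data)
    if missing:
        raise KeyError(f"missing parameter key(s): {sorted(missing)}")
    return ParameterSet(**{k: float(v) for k, v in data.items()})


def mask_to_yaml(mask: ConnectionMask, path=None) -> str:
    data = {name: bool(getattr(mask, name)) for name in EDGE_NAMES}
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def mask_from_yaml(source) -> ConnectionMask:
    text = Path(source).read_text() if not _is_yaml_text(source) else source
    data = yaml.safe_load(text)
    unknown = set(data) - set(EDGE_NAMES)
    if unknown:
        raise KeyError(f"unknown edge key(s): {sorted(unknown)}")
    return ConnectionMask(**{k: bool(v) for k, v in data.items()})


def _is_yaml_text(source) -> bool:
    return isinstance(source, str) and ("\n" in source or ":" in source)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# time courses and generic tables
# ---------------------------------------------------------------------------

def write_timecourse(tc, path) -> None:
    header_lines = [
        "# regcycle time course",
        f"# inputs: stress={tc.inputs.stress:.12g} "
        f"mtor_total={tc.inputs.mtor_total:.12g}",
        "# params: " + json.dumps({k: float(v) for k, v in tc.params.items()}),
        "# mask: " + json.dumps({n: bool(getattr(tc.mask, n))
                                 for n in EDGE_NAMES}),
        "time\t" + "\t".join(STATE_NAMES),
    ]
    body = "\n".join(
        "\t".join(FLOAT_FMT % v for v in row)
        for row in np.column_stack([tc.t, tc.states]))
    Path(path).write_text("\n".join(header_lines) + "\n" + body + "\n")


def read_timecourse(path):
    from .dynamics import TimeCourse

    params_d = mask_d = None
    inputs = SystemInputs()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# params: "):
                params_d = json.loads(line[len("# params: "):])
            elif line.startswith("# mask: "):
                mask_d = json.loads(line[len("# mask: "):])
            elif line.startswith("# inputs:"):
                parts = dict(p.split("=") for p in line.split()[2:])
                inputs = SystemInputs(float(parts["stress"]),
                                      float(parts["mtor_total"]))
    df = pd.read_csv(path, sep="\t", comment="#")
    params = ParameterSet(**params_d) if params_d else None
    mask = ConnectionMask(**mask_d) if mask_d else ConnectionMask.full()
    return TimeCourse(df["time"].to_numpy(),
                      df[list(STATE_NAMES)].to_numpy(), inputs, params, mask)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """TSV with optional provenance comment header."""
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
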