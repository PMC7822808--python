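"""Model configuration files (JSON/YAML) and tabular/JSON result output.

The model format::

    {"L": 2, "M": [2, 2], "h": [...], "J": [[...]] or {"(l,r)": [[...]]},
     "theta": [...], "P": [[[...]]], "pim_u": [[...]]}

``J`` may be given as a full matrix or as upper-triangular blocks keyed by
1-based ``"(l,r)"`` pairs, which are mirrored automatically.  Tables are
written as TSV (header, '.' decimal, UTF-8, deterministic row order);
structured reports as JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml

from .examples import random_model
from .model import ModelSpec, validate_model

__all__ = [
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "make_fixture_model",
    "write_table",
    "write_json",
]

# spec-facing alias: random fixture model generation
make_fixture_model = random_model

_BLOCK_KEY = re.compile(r"^\((\d+)\s*,\s*(\d+)\)$")


def model_from_dict(d: dict) -> ModelSpec:
    """Build and validate a ModelSpec from a parsed config mapping."""
    M = tuple(int(m) for m in d["M"])
    L = int(d.get("L", len(M)))
    if L != len(M):
        raise ValueError(f"L = {L} does not match len(M) = {len(M)}")
    mtot = sum(M)
    offsets = np.concatenate([[0], np.cumsum(M)])
    J_raw = d.get("J", None)
    if J_raw is None:
        J = np.zeros((mtot, mtot))
    elif isinstance(J_raw, dict):
        J = np.zeros((mtot, mtot))
        for key, block in J_raw.items():
            m = _BLOCK_KEY.match(key.strip())
            if not m:
                raise ValueError(f"bad J block key {key!r}; expected '(l,r)'")
            l, r = int(m.group(1)) - 1, int(m.group(2)) - 1
            if not (0 <= l < r < L):
                raise ValueError(f"J block key {key!r} must have 1 <= l < r <= L")
            b = np.asarray(block, float)
            if b.shape != (M[l], M[r]):
                raise ValueError(
                    f"J block {key!r} has shape {b.shape}, expected {(M[l], M[r])}"
                )
            J[offsets[l] : offsets[l + 1], offsets[r] : offsets[r + 1]] = b
            J[offsets[r] : offsets[r + 1], offsets[l] : offsets[l + 1]] = b.T
    else:
        J = np.asarray(J_raw, float)
    h = np.asarray(d.get("h", np.zeros(mtot)), float)
    pim_u = d.get("pim_u", None)
    if pim_u is not None:
        pim_u = tuple(np.asarray(u, float) for u in pim_u)
    theta = d.get("theta", None)
    P = d.get("P", None)
    if theta is not None and P is None:
        raise ValueError("theta given without P")
    spec = ModelSpec(
        M=M,
        h=h,
        J=J,
        theta=None if theta is None else np.asarray(theta, float),
        P=None if P is None else tuple(np.asarray(p, float) for p in P),
        pim_u=pim_u,
    )
    errs = validate_model(spec)
    if errs:
        raise ValueError("invalid model:\n  " + "\n  ".join(errs))
    return spec


def model_to_dict(spec: ModelSpec) -> dict:
    d = {
        "L": spec.L,
        "M": list(spec.M),
        "h": spec.h.tolist(),
        "J": spec.J.tolist(),
        "theta": spec.theta.tolist(),
        "P": [p.tolist() for p in spec.P],
    }
    if spec.pim_u is not None:
        d["pim_u"] = [u.tolist() for u in spec.pim_u]
    return d


def load_model(path) -> ModelSpec:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    return model_from_dict(d)


def save_model(spec: ModelSpec, path) -> None:
    path = Path(path)
    d = model_to_dict(spec)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def write_table(records, path, columns) -> None:
    """Write records (sequence of mappings) as TSV with a fixed column order."""
    path = Path(path)
    lines = ["\t".join(columns)]
    for rec in records:
        lines.append("\t".join(_fmt(rec[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return ",".join(str(x) for x in v)
    return str(v)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
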