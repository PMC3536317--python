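"""Configuration parsing and report/trajectory writers.

Configs are flat YAML (or JSON, a YAML subset) with the transliterated
rate symbols as keys::

    model: estrogen
    params: {alpha1: 0.7, beta1: 0.3, ..., pi_src: 0.2, theta: 0.97}
    init: ic_estrogen_paper      # preset name, or an explicit list
    t_end: 100.0
    rtol: 1.0e-8
    atol: 1.0e-10

Omitted parameters fall back to the canonical presets.  Every command
writes a manifest echoing the fully-resolved configuration so any
output can be reproduced from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .models import InvalidInputError, validate_params
from .presets import (
    DEFAULT_ESTROGEN_PARAMS,
    DEFAULT_T_END,
    IC_PRESETS,
    TABLE1_PARAMS,
)
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, Trajectory


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config must be a mapping, got {type(cfg).__name__}")
    return cfg


def resolve_config(cfg: dict) -> dict:
    """Fill defaults and validate; returns the fully-resolved config.

    The result contains the validated parameter set (``params_obj``),
    the initial state (``init_state``) and plain-data echoes of both
    for the manifest.
    """
    model = cfg.get("model", "estrogen_free")
    if model not in ("estrogen_free", "estrogen"):
        raise InvalidInputError(f"unknown model {model!r}")
    base = TABLE1_PARAMS if model == "estrogen_free" else DEFAULT_ESTROGEN_PARAMS
    raw = base.to_dict()
    overrides = cfg.get("params", {}) or {}
    if not isinstance(overrides, dict):
        raise InvalidInputError("config key 'params' must be a mapping")
    raw.update({k: float(v) for k, v in overrides.items()})
    params = validate_params(raw, model)

    init_spec = cfg.get(
        "init",
        "ic_estrogen_free_paper" if model == "estrogen_free" else "ic_estrogen_paper",
    )
    if isinstance(init_spec, str):
        if init_spec not in IC_PRESETS:
            raise InvalidInputError(
                f"unknown initial-condition preset {init_spec!r}; "
                f"known: {sorted(IC_PRESETS)}"
            )
        init = IC_PRESETS[init_spec]
    else:
        init = np.asarray(init_spec, dtype=float)
    expected = 3 if model == "estrogen_free" else 4
    if init.shape != (expected,):
        raise InvalidInputError(
            f"init must have {expected} components for model {model!r}"
        )

    resolved = {
        "model": model,
        "params": params.to_dict(),
        "init": [float(x) for x in init],
        "t_end": float(cfg.get("t_end", DEFAULT_T_END[model])),
        "rtol": float(cfg.get("rtol", DEFAULT_RTOL)),
        "atol": float(cfg.get("atol", DEFAULT_ATOL)),
        "seed": int(cfg.get("seed", 0)),
        "params_obj": params,
        "init_state": init,
    }
    if not resolved["t_end"] > 0:
        raise InvalidInputError(f"t_end must be positive, got {resolved['t_end']}")
    for key in ("pi_grid", "noise_sd", "free_names", "boundary"):
        if key in cfg:
            resolved[key] = cfg[key]
    return resolved


def manifest_dict(resolved: dict) -> dict:
    return {k: v for k, v in resolved.items() if not k.endswith("_obj") and k != "init_state"}


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    """CSV dialect: header t,H,T,I[,E]; one row per saved point."""
    header = ["t", "H", "T", "I"]
    if traj.states.shape[1] == 4:
        header.append("E")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([traj.times, traj.states])
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in data:
            fh.write(",".join(f"{x:.12g}" for x in row) + "\n")


def read_trajectory_csv(path: str | Path):
    """Inverse of :func:`write_trajectory_csv`: (times, states) arrays."""
    raw = np.genfromtxt(path, delimiter=",", names=True)
    times = raw["t"]
    cols = [n for n in ("H", "T", "I", "E") if n in raw.dtype.names]
    states = np.column_stack([raw[c] for c in cols])
    return times, states


def equilibria_report(params, with_stability: bool = True) -> dict:
    """JSON-ready report: all equilibria, local stability, global verdict."""
    from .equilibria import all_equilibria
    from .stability import castillo_chavez_global, local_stability

    eqs = all_equilibria(params)
    entries = []
    for eq in eqs:
        entry = eq.to_dict()
        if with_stability and np.all(np.isfinite(eq.state)):
            entry["stability"] = local_stability(eq, params).to_dict()
        entries.append(entry)
    report = {
        "model": params.model,
        "equilibria": entries,
        "global": castillo_chavez_global(params).to_dict(),
    }
    return report


def equilibria_report_rows(report: dict) -> list[dict]:
    """Flatten an equilibria report into CSV-ready rows."""
    rows = []
    for e in report["equilibria"]:
        state = e["state"]
        row = {
            "label": e["label"],
            "model": e["model"],
            "feasible": e["feasible"],
            "residual": e["residual"],
            "H": state[0],
            "T": state[1],
            "I": state[2],
        }
        if len(state) == 4:
            row["E"] = state[3]
        stab = e.get("stability")
        row["classification"] = stab["classification"] if stab else ""
        rows.append(row)
    return rows
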