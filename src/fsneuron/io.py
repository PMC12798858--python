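"""Configuration loading/validation, trace CSV I/O and run manifests.

Configs are YAML/JSON with sections ``geometry``, ``ais``, ``channels``,
``simulation``.  Validation is strict: unknown keys are rejected (not
ignored) and error messages name the offending key.  Traces are stored as
CSV with the fixed header ``time_ms,v_soma_mV[,v_ais_mV],i_stim_pA,
g_syn_nS`` at six significant digits; a ``sweep_id`` column marks
multi-sweep files.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cell import CellModel, ConfigError, VoltageTrace

__all__ = [
    "load_config",
    "config_digest",
    "write_trace",
    "read_trace",
    "read_sweeps",
    "write_sweeps",
    "RunManifest",
]

_GATE_KEYS = {
    "v_half_mV", "v_slope_mV", "tau_max_ms", "tau_min_ms",
    "v_tau_half_mV", "v_tau_slope_mV",
}
_SCHEMA = {
    "geometry": {
        "soma": {"cm_total_pF", "leak_resistance_MOhm"},
        "axon": {"length_um", "diameter_um", "segment_length_um",
                 "cm_fF_per_um2", "ra_MOhm_per_um"},
        "dendrite": {"length_um", "diameter_um", "segment_length_um",
                     "cm_fF_per_um2", "ra_MOhm_per_um", "proximal_fraction"},
        "e_leak_mV": None,
    },
    "ais": {"start_um", "length_um", "gnav16_nS_per_um2", "gkv1_nS_per_um2"},
    "simulation": {"dt_ms", "v_hold_mV", "settle_ms"},
}
_CHANNEL_KEYS = {"p", "e_mV", "regions", "activation", "inactivation"}
_REGION_KEYS = {"ais", "soma", "dendrite", "dendrite_proximal"}


def _check_keys(d: dict, allowed, path: str) -> None:
    for k in d:
        if k not in allowed:
            raise ConfigError(f"unknown key {path}.{k!r} (allowed: {sorted(allowed)})")


def _require_number(val, path: str, nonneg: bool = False) -> float:
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        raise ConfigError(f"{path} must be a number, got {type(val).__name__}")
    if nonneg and val < 0:
        raise ConfigError(f"{path} must be non-negative, got {val}")
    return float(val)


def validate_config(cfg: dict) -> dict:
    """Strict schema validation; returns the config unchanged on success."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, set(_SCHEMA) | {"channels"}, "config")
    for sect in ("geometry", "channels"):
        if sect not in cfg:
            raise ConfigError(f"missing required section {sect!r}")

    geo = cfg["geometry"]
    _check_keys(geo, set(_SCHEMA["geometry"]), "geometry")
    if "soma" not in geo:
        raise ConfigError("geometry.soma is required")
    _check_keys(geo["soma"], _SCHEMA["geometry"]["soma"], "geometry.soma")
    for sec in ("axon", "dendrite"):
        if geo.get(sec) is not None:
            _check_keys(geo[sec], _SCHEMA["geometry"][sec], f"geometry.{sec}")
            for k, v in geo[sec].items():
                _require_number(v, f"geometry.{sec}.{k}")

    if cfg.get("ais") is not None:
        _check_keys(cfg["ais"], _SCHEMA["ais"], "ais")
        for k, v in cfg["ais"].items():
            _require_number(v, f"ais.{k}", nonneg=k.startswith("g") or k == "start_um")

    for name, ch in cfg["channels"].items():
        path = f"channels.{name}"
        _check_keys(ch, _CHANNEL_KEYS, path)
        if "p" not in ch or "e_mV" not in ch:
            raise ConfigError(f"{path}: 'p' and 'e_mV' are required")
        _check_keys(ch.get("regions", {}), _REGION_KEYS, f"{path}.regions")
        for region, val in ch.get("regions", {}).items():
            if isinstance(val, str):
                if val not in ("from_ais_nav16", "from_ais_kv1"):
                    raise ConfigError(
                        f"{path}.regions.{region}: unknown symbolic density {val!r}"
                    )
            else:
                _require_number(val, f"{path}.regions.{region}", nonneg=True)
        for gate in ("activation", "inactivation"):
            if ch.get(gate) is not None:
                _check_keys(ch[gate], _GATE_KEYS, f"{path}.{gate}")
                missing = _GATE_KEYS - set(ch[gate])
                if missing:
                    raise ConfigError(f"{path}.{gate}: missing {sorted(missing)}")

    if "simulation" in cfg:
        _check_keys(cfg["simulation"], _SCHEMA["simulation"], "simulation")
    return cfg


def load_config(path: Union[str, Path]) -> dict:
    """Load and validate a YAML/JSON model configuration file."""
    path = Path(path)
    with open(path) as f:
        if path.suffix == ".json":
            cfg = json.load(f)
        else:
            cfg = yaml.safe_load(f)
    try:
        return validate_config(cfg)
    except ConfigError as e:
        raise ConfigError(f"{path}: {e}") from None


def config_digest(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# trace CSV
# --------------------------------------------------------------------------

def _trace_frame(trace: VoltageTrace) -> pd.DataFrame:
    cols = {"time_ms": trace.t}
    for j, name in enumerate(trace.channels):
        key = "v_soma_mV" if name == "soma" else f"v_{name}_mV"
        cols[key] = trace.vm[:, j]
    cols["i_stim_pA"] = (trace.i_stim if trace.i_stim is not None
                         else np.zeros(len(trace)))
    cols["g_syn_nS"] = (trace.g_syn if trace.g_syn is not None
                        else np.zeros(len(trace)))
    return pd.DataFrame(cols)


def write_trace(trace: VoltageTrace, path: Union[str, Path]) -> None:
    """Write one trace as CSV (floats at 6 significant digits)."""
    _trace_frame(trace).to_csv(path, index=False, float_format="%.6g")


def write_sweeps(traces: Sequence[VoltageTrace], path: Union[str, Path]) -> None:
    """Write several sweeps into one CSV distinguished by ``sweep_id``."""
    frames = []
    for i, tr in enumerate(traces):
        df = _trace_frame(tr)
        df.insert(0, "sweep_id", i)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.6g")


def _frame_to_trace(df: pd.DataFrame, path) -> VoltageTrace:
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_ms'")
    vcols = [c for c in df.columns if c.startswith("v_") and c.endswith("_mV")]
    if "v_soma_mV" not in vcols:
        raise ValueError(f"{path}: missing required column 'v_soma_mV'")
    t = df["time_ms"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or not np.allclose(dts, dt, rtol=1e-3, atol=1e-6):
        raise ValueError(f"{path}: non-uniform time base")
    names = tuple("soma" if c == "v_soma_mV" else c[2:-3] for c in vcols)
    vm = df[vcols].to_numpy(float)
    i_stim = df["i_stim_pA"].to_numpy(float) if "i_stim_pA" in df else None
    g_syn = df["g_syn_nS"].to_numpy(float) if "g_syn_nS" in df else None
    return VoltageTrace(dt=dt, t0=float(t[0]), vm=vm, channels=names,
                        i_stim=i_stim, g_syn=g_syn)


def read_trace(path: Union[str, Path]) -> VoltageTrace:
    """Read a single-sweep trace CSV."""
    df = pd.read_csv(path)
    if "sweep_id" in df.columns:
        raise ValueError(f"{path}: multi-sweep file; use read_sweeps()")
    return _frame_to_trace(df, path)


def read_sweeps(path: Union[str, Path]) -> list[VoltageTrace]:
    """Read a multi-sweep trace CSV (``sweep_id`` column) into one trace per sweep."""
    df = pd.read_csv(path)
    if "sweep_id" not in df.columns:
        return [_frame_to_trace(df, path)]
    return [
        _frame_to_trace(g.drop(columns="sweep_id"), f"{path}[sweep {sid}]")
        for sid, g in df.groupby("sweep_id", sort=True)
    ]


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

class RunManifest:
    """Provenance record for a pipeline run: config digest, seeds, stages."""

    def __init__(self, config: Optional[dict] = None, seed: Optional[int] = None):
        from . import __version__

        self.data = {
            "package": "fsneuron",
            "version": __version__,
            "config_digest": config_digest(config) if config else None,
            "seed": seed,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "platform": platform.platform(),
            "stages": [],
            "warnings": [],
        }

    def stage(self, name: str, status: str = "ok", **info) -> None:
        self.data["stages"].append({"name": name, "status": status, **info})

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as f:
            json.dump(self.data, f, indent=2)
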