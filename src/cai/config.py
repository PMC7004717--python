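"""Flat YAML run configuration.

One file, one section per module, so the calibration constants that
matter most (K, M, epoch geometry, simulator levels) can be swept from
the command line without touching code.  CLI flags override file
values; anything unspecified falls back to the library defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .entropy import SpenParams
from .index import CaiParams, EpochingParams, ThresholdParams
from .io import ValidationError
from .simulate import SimConfig

__all__ = [
    "load_config",
    "cai_params_from",
    "spen_params_from",
    "sim_config_from",
    "config_hash",
]


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping of sections")
    return data


def cai_params_from(cfg: dict[str, Any]) -> CaiParams:
    sec = cfg.get("cai", {})
    return CaiParams(
        epoching=EpochingParams(
            epoch_len=int(sec.get("epoch_len", 512)),
            step=int(sec.get("step", 256)),
        ),
        threshold=ThresholdParams(
            K=float(sec.get("K", 6.0)), M=int(sec.get("M", 16))
        ),
        smooth_epochs=int(sec.get("smooth_epochs", 15)),
    )


def spen_params_from(cfg: dict[str, Any]) -> SpenParams:
    sec = cfg.get("spen", {})
    return SpenParams(
        band=(float(sec.get("band_lo", 0.8)), float(sec.get("band_hi", 32.0))),
        epoching=EpochingParams(
            epoch_len=int(sec.get("epoch_len", 1024)),
            step=int(sec.get("step", 256)),
        ),
        smooth_epochs=int(sec.get("smooth_epochs", 15)),
    )


def sim_config_from(cfg: dict[str, Any], seed: int | None = None) -> SimConfig:
    sec = dict(cfg.get("sim", {}))
    if seed is not None:
        sec["seed"] = seed
    known = {
        f: sec[f]
        for f in (
            "n_sources", "fs", "tau_up0", "tau_down0", "firing_rate_up",
            "delta_hz", "delta_mod", "psp_tau", "psp_amp", "noise_pink",
            "noise_white", "hp_hz", "floor_up", "floor_down", "seed",
        )
        if f in sec
    }
    return SimConfig(**known)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a resolved configuration."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
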