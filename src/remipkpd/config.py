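"""Structured configuration: YAML/JSON overrides for fixed effects, IIV and
PD shape parameters."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .covariates import IIVSpec, ThetaTable

__all__ = ["load_config", "theta_from_config", "iiv_from_config", "config_hash"]


def load_config(path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) config mapping."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def _apply(cls_instance, overrides: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls_instance)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown {what} fields: {sorted(unknown)}")
    return dataclasses.replace(cls_instance, **{k: float(v) for k, v in overrides.items()})


def theta_from_config(cfg: dict, base: ThetaTable | None = None) -> ThetaTable:
    """ThetaTable with the ``theta:`` section of a config applied on top."""
    return _apply(base or ThetaTable(), cfg.get("theta", {}), "theta")


def iiv_from_config(cfg: dict, base: IIVSpec | None = None) -> IIVSpec:
    return _apply(base or IIVSpec(), cfg.get("iiv", {}), "IIV")


def config_hash(cfg: dict) -> str:
    """Short stable hash for provenance headers."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
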