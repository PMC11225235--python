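"""Pipeline configuration: YAML with a full default set, CLI flags override."""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ValidationError
from .simulate import DEFAULT_COHORT_CONFIG

DEFAULTS: dict = {
    "paths": {"regions": None, "atlas": None, "manifest": None},
    "thresholds": {
        "cfdna_min": 0.40,
        "etf_min": 0.30,
        "min_depth_per_cpg": 1,
        "min_cpgs_per_cluster": 3,
        "min_clusters": 50,
        "cnv_z": 3.0,
        "cnv_min_bins": 5,
        "min_panel_median": 10.0,
    },
    "binsize": 400_000,
    "seed": 0,
    "simulate": dict(DEFAULT_COHORT_CONFIG),
}

_THRESHOLD_RANGES = {
    "cfdna_min": (0.0, 1.0),
    "etf_min": (0.0, 1.0),
    "min_depth_per_cpg": (1, None),
    "min_cpgs_per_cluster": (1, None),
    "min_clusters": (1, None),
    "cnv_z": (0.0, None),
    "cnv_min_bins": (1, None),
    "min_panel_median": (0.0, None),
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the package defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        cfg = _deep_merge(DEFAULTS, user)
    _validate_thresholds(cfg.get("thresholds", {}))
    if cfg.get("binsize", 1) <= 0:
        raise ValidationError("binsize must be positive")
    return cfg


def _validate_thresholds(thresholds: dict) -> None:
    for key, (lo, hi) in _THRESHOLD_RANGES.items():
        if key not in thresholds:
            continue
        val = thresholds[key]
        if val < lo or (hi is not None and val > hi):
            raise ValidationError(f"threshold {key}={val} outside documented range")


def resolve_paths(cfg: dict, base) -> dict:
    """Resolve configured paths relative to ``base`` and require existence."""
    base = Path(base)
    out = {}
    for key, val in cfg.get("paths", {}).items():
        if val is None:
            out[key] = None
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if key == "atlas":
            exists = p.with_suffix(".csv").exists() or Path(f"{p}.csv").exists()
        else:
            exists = p.exists()
        if not exists:
            raise ValidationError(f"configured path {key}={val!r} does not exist")
        out[key] = p
    return out
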