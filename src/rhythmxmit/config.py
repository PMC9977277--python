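"""Flat, dotted-key configuration for the analysis pipeline.

All tunable thresholds live here so a run is reproducible from its effective
config alone.  Keys are dotted strings (``detect.k_on``); values are plain
scalars so the whole config round-trips through YAML.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: Package defaults.  Units are seconds, Hz, mV, pA as indicated by key names.
DEFAULTS: dict[str, Any] = {
    # rectify-integrate
    "integrate.tau_s": 0.05,
    "integrate.center": True,
    # burst detection (hysteresis, in robust-spread multiples above baseline)
    "detect.k_on": 4.0,
    "detect.k_off": 2.0,
    "detect.min_duration_s": 0.1,
    "detect.merge_gap_s": 0.2,
    # irregularity score
    "irs.feature": "peak_amplitude",  # or "area"
    "irs.scaled": False,              # True multiplies the score by 100
    # subnetwork classification
    "subnetwork.threshold_fraction": 0.5,
    "subnetwork.feature": "area",     # or "peak_amplitude"
    # cross-site correspondence
    "match.w_min_s": 0.5,
    "match.w_max_s": 0.75,
    "match.grid_step_s": 0.01,
    "match.directional": False,
    # analysis window
    "window.duration_s": 120.0,
    # I/O summary
    "io.include_failures": True,
    # histogram / heat map
    "hist.bin_width": 0.1,
    "hist.norm_basis": "own_window",  # or "baseline_phase"
    "heatmap.max_cycles": 25,
    # patch metrics
    "ap.threshold_mv": -20.0,
    "ap.refractory_s": 0.002,
    "drive.search_window_s": 1.0,
    "drive.k_noise": 4.0,
    "ramp.rate_pa_s": 122.0,
    "ramp.peak_pa": 600.0,
    "ramp.prestep_pa": -100.0,
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Return the effective config: defaults <- YAML file <- overrides.

    The YAML file may be flat (dotted keys) or nested; nested mappings are
    flattened with '.' separators.  Unknown keys raise :class:`ConfigError`
    so typos never silently fall back to a default.
    """
    cfg = copy.deepcopy(DEFAULTS)
    merged: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        merged.update(_flatten(loaded))
    if overrides:
        merged.update(dict(overrides))
    for key, value in merged.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key!r}")
        cfg[key] = value
    return cfg


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    """Write the effective (flat) config as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in mapping.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, prefix=f"{name}."))
        else:
            out[name] = value
    return out
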