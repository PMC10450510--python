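"""Single configuration surface for every threshold used downstream.

Values mirror the analysis defaults (classification widths, burst window,
SPA windows, crosscorrelogram gates, ...) so they are configuration, not
constants buried in code.  ``load_config`` merges a YAML file over the
defaults; unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "epochs": {
        "guard_s": 30.0,
        "target_s": 300.0,
    },
    "rule_set": {  # unit classification
        "pc_width_ms": 0.4,
        "in_width_ms": 0.2,
        "ib_peak_lo_ms": 3.0,
        "ib_peak_hi_ms": 10.0,
        "acg_bin_ms": 1.0,
        "acg_window_ms": 50.0,
        "peak_prominence_factor": 2.0,
        "peak_min_count": 5,
        "decay_tau_max_ms": 20.0,
        "sustained_rate_min_hz": 0.5,
    },
    "bursts": {
        "window_ms": 20.0,
        "min_spikes": 3,
    },
    "spa": {
        "baseline_ms": [-150.0, -50.0],
        "peri_ms": [-50.0, 50.0],
        "amplitude_window_ms": [-50.0, 50.0],
    },
    "modulation": {
        "alpha": 0.05,
        "min_events": 10,
        "change_gate": 0.5,  # |relative change| must reach 50%
        "granger_bin_ms": 10.0,
        "granger_max_order": 10,
    },
    "connectivity": {
        "window_ms": 40.0,
        "bin_ms": 1.0,
        "baseline_lo_ms": 20.0,
        "baseline_hi_ms": 40.0,
        "sd_factor": 2.0,
        "min_peak_count": 20,
        "mono_lo_ms": 1.0,
        "mono_hi_ms": 3.0,
    },
    "cell_counting": {
        "resize_factor": 0.5,
        "denoise_sigma": 1.0,
        "block_size": 51,
        "threshold_offset": 0.0,
        "blur_sigma": 1.0,
        "morph_radius": 1,
        "open_iterations": 1,
        "dilate_iterations": 1,
        "canny_sigma": 1.0,
        "size_sd_band": 2.0,
        "section_thickness_um": 60.0,
        "density_unit_um3": 1.0e6,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    for key, val in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            _merge(base[key], val, path + key + ".")
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        _merge(cfg, override)
    return cfg
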