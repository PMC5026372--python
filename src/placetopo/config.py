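"""Default configuration and YAML/JSON overrides for the pipeline.

Every tunable named across the package has a key here; a config file needs
to supply only the keys it overrides.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "lfp": {
        "duration_s": 1500.0,
        "fs_hz": 1000.0,
        "theta_hz": 8.0,
        "gamma_band_hz": [30.0, 80.0],
        "theta_jitter": 0.10,
        "gamma_burst_sigma": 0.25,
        "gamma_burst_hz": 1.3,
        "seed": 0,
    },
    "arena": {
        "width_m": 1.0,
        "height_m": 1.0,
        # axis-aligned rectangles (x0, y0, x1, y1); default 25 cm central square
        "obstacles": [[0.375, 0.375, 0.625, 0.625]],
    },
    "trajectory": {
        "duration_s": 1500.0,
        "dt_s": 0.001,
        "mean_speed_mps": 0.20,
        "heading_persistence_s": 1.0,
        "seed": 0,
    },
    "ensemble": {
        "s_m": 0.08,  # mean Gaussian width; mean field extent = 3*s = 0.24 m
        "f_hz": 20.0,
        "N": 450,
        "a": 0.25,
        "b": 0.25,
        "seed": 0,
    },
    "spiking": {
        "beta": 0.0,
        "dt_s": 0.001,
        "gamma_normalization": "raw",  # raw | cell | session
        "seed": 0,
        "lambda_theta_normalized": True,
    },
    "complexes": {
        "w_s": 0.25,  # 2 * theta period
        "step_s": None,  # default w/2
        "min_spikes": 1,
        "horizon_s": 600.0,
        "kind": "simplicial",
    },
    "topology": {
        "grid_step_s": 15.0,
        "target_betti": [1, 1],
    },
    "sweep": {
        "betas": [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0],
        "window_theta_factors": [2.0, 1.2, 0.8, 0.5, 0.3, 0.2],
        "include_gamma_window": True,
        "n_seeds": 5,
        "master_seed": 0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """DEFAULTS merged with a YAML or JSON override file (if given)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text()
    override = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if override is None:
        override = {}
    if not isinstance(override, dict):
        raise ValueError("config file must hold a mapping at top level")
    return _deep_merge(DEFAULTS, override)
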