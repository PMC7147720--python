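"""JSON pipeline configuration with complete defaults.

Every block has a full default; unknown keys anywhere in the tree are
rejected so a typo never silently falls back to a default.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grayscale": {"weights": [0.2989, 0.5870, 0.1140]},
    "resize": {"kernel": "bilinear"},
    "hair_removal": {
        "enabled": True,
        "se_lengths": [9],
        "se_angles": [0.0, 45.0, 90.0, 135.0],
        "detect_threshold": 25,
        "min_elongation": 3.0,
        "min_length": 15,
        "median_window": 7,
        "max_width": 7.0,
    },
    "segmentation": {
        "window_fraction": 0.5,
        "sensitivity": 0.8,
        "foreground_polarity": "dark",
    },
    "hog": {
        "cell_size": [4, 4],
        "block_size": [2, 2],
        "bins": 9,
        "signed": False,
        "window_size": [128, 128],
    },
    "classifiers": {
        "mlp": {"hidden_units": 72, "input_side": 32, "max_epochs": 300},
        "hog_svm": {"crop": True},
        # stand-ins for externally fine-tuned CNNs: simulated decision
        # tables with these per-image error rates
        "externals": [
            {"name": "cnn_a", "error_rate": 0.10},
            {"name": "cnn_b", "error_rate": 0.10},
            {"name": "cnn_c", "error_rate": 0.12},
        ],
    },
    "fusion": {"weights": "from-validation", "threshold_factor": 0.7, "weight_precision": 2},
    "synth": {"profile": "ph2", "hair_fraction": 0.3, "size": [560, 768]},
}


def _check_unknown(given: dict, default: dict, path: str = "") -> None:
    for key, value in given.items():
        if key not in default:
            raise ValueError(f"unknown config key: {path + key!r}")
        if isinstance(default[key], dict) and isinstance(value, dict):
            _check_unknown(value, default[key], path + key + ".")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a JSON file and/or a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        _check_unknown(user, DEFAULT_CONFIG)
        cfg = _merge(cfg, user)
    if overrides:
        _check_unknown(overrides, DEFAULT_CONFIG)
        cfg = _merge(cfg, overrides)
    return cfg
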