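"""Configuration defaults and YAML overrides.

Precedence: command-line flags > configuration file > built-in defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .errors import InputError

DEFAULTS: dict[str, Any] = {
    "weights": {"dc": 20.0, "cf": 0.001, "fsc": 0.01},
    "descriptors": {"gaps": [0, 1]},
    "fourier": {"n_components": 10},
    "min_length": 21,
    "fknn": {"K": 3, "m": 2.0},
    "grid": {
        "K": list(range(1, 16)),
        "m": [round(v, 1) for v in np.arange(1.1, 3.01, 0.1)],
    },
    "scales_path": None,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str] = None) -> dict[str, Any]:
    """Defaults merged with an optional YAML configuration file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read config {path!r}: {exc}") from exc
    loaded = yaml.safe_load(text) or {}
    if not isinstance(loaded, dict):
        raise InputError(f"config {path!r} must be a YAML mapping")
    return _merge(DEFAULTS, loaded)


def parse_range(text: str, integer: bool = False) -> list:
    """Parse ``start:stop[:step]`` or a comma list into a grid of values."""
    if ":" in text:
        parts = [float(p) for p in text.split(":")]
        if len(parts) == 2:
            start, stop = parts
            step = 1.0
        elif len(parts) == 3:
            start, stop, step = parts
        else:
            raise InputError(f"bad range {text!r}; expected start:stop[:step]")
        values = np.arange(start, stop + step / 2, step)
    else:
        values = np.array([float(p) for p in text.split(",") if p.strip()])
    if values.size == 0:
        raise InputError(f"empty grid {text!r}")
    if integer:
        return [int(round(v)) for v in values]
    return [round(float(v), 10) for v in values]
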