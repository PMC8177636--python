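"""Single home for every default parameter used by the pipeline.

All documented defaults live here so the CLI, the config loader and the
library agree; ``resolve_config`` merges a (possibly partial) user config
over these defaults and returns the effective configuration that is written
next to every set of outputs.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "model": "solid",                 # solid | shell
    "pixel_size": 0.215,              # μm / pixel
    "elastic": {
        "youngs_modulus": 5000.0,     # Pa
        "poisson_ratio": 0.5,         # incompressible
        "shell_thickness": 0.1,       # μm (shell model energy only)
        "strain_convention": "as-printed",  # or green-lagrange
    },
    "anneal": {
        "initial_acceptance": 0.2,
        "cooling_factor": 0.95,
        "sweeps_max": 500,
        "stall_sweeps": 25,
        "move_fraction": 0.1,
        "temperature": None,          # None => calibrated
        "n_points": None,             # None => target point count
        "reproject": True,            # keep mapped points on the target outline
    },
    "channel": {
        "channel_width": 7.0,         # μm
        "channel_height": 4.7,
        "constriction_width": 2.0,
        "constriction_height": 3.4,
        "constriction_length": 20.0,
        "taper_angle_deg": 45.0,
        "constriction_start": 0.0,
    },
    "plots": {
        "enabled": False,
        "arrow_pa_per_um": 250.0,     # one unit of length = 250 Pa
        "format": "png",
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(user: Mapping | None = None) -> dict:
    """Merge a user config over the package defaults (deep merge)."""
    return _merge(DEFAULTS, user or {})
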