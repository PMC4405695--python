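"""Run configuration: defaults, named presets, YAML round-trip.

Every pipeline parameter has a default here; a config file only needs
to state deviations.  Unknown keys are rejected by name so typos never
silently fall back to defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

# Named constants of the assays.
FRAME_INTERVAL_PRESETS = {
    "vesicle": 2.0,    # s, live-cell vesicle imaging cadence
    "tirf": 0.041,     # s, streaming single-molecule TIRF
}
AREA_THRESHOLD_PRESETS = {
    "sirna": 4.11,       # µm², large-object cutoff in siRNA-rescue scoring
    "nocodazole": 2.74,  # µm², cutoff for nocodazole-fragmented Golgi
}

DEFAULTS: dict = {
    "seed": 0,
    "stages": ["simulate", "motion"],
    "io": {
        "outdir": "vesitrack_out",
    },
    "simulate": {
        "n_tracks": 50,
        "mode": "confined",
        "diffusion_coefficient": 0.05,
        "confinement_radius": 0.3,
        "speed": 0.5,
        "reversal_rate": 0.05,
        "pause_rate": 0.0,
        "pause_duration_mean": 4.0,
        "frame_interval": FRAME_INTERVAL_PRESETS["vesicle"],
        "n_frames": 71,
        "localization_noise_sd": 0.02,
    },
    "motion": {
        "alpha_confined": 0.7,
        "alpha_linear": 1.3,
        "min_points": 20,
        "pause_speed_threshold": 0.1,
        "frame_interval": FRAME_INTERVAL_PRESETS["vesicle"],
    },
    "detect": {
        "intensity_threshold": 50.0,
        "min_separation": 3.0,
        "pixel_size": 0.1,
    },
    "link": {
        "max_disp": 0.5,
        "max_gap": 0,
        "frame_interval": FRAME_INTERVAL_PRESETS["tirf"],
    },
    "tirf": {
        "speed_min": 0.12,
        "distance_min": 0.2,
        "duration_min": 0.9,
        "frame_interval": FRAME_INTERVAL_PRESETS["tirf"],
        "dilation_px": 1,
    },
    "golgi": {
        "preset": "sirna",
        "area_threshold": None,  # overrides the preset when set
        "method": "otsu",
        "threshold": None,
        "min_object_area": 0.1,
        "intensity_weighted": True,
    },
    "bind": {
        "normalize": False,
        "model": "hyperbola",
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key '{here}'")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


class RunConfig:
    """Validated parameter tree; attribute-style section access."""

    def __init__(self, overrides: dict | None = None):
        self._data = _merge(DEFAULTS, overrides or {})

    def __getitem__(self, key: str):
        return self._data[key]

    def section(self, name: str) -> dict:
        return copy.deepcopy(self._data[name])

    @property
    def data(self) -> dict:
        return copy.deepcopy(self._data)

    def golgi_area_threshold(self) -> float:
        g = self._data["golgi"]
        if g["area_threshold"] is not None:
            return float(g["area_threshold"])
        preset = g["preset"]
        if preset not in AREA_THRESHOLD_PRESETS:
            raise ValueError(f"unknown golgi preset '{preset}'")
        return AREA_THRESHOLD_PRESETS[preset]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(data)

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self._data == other._data
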