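"""Experiment configuration: load, validate, and echo.

A config (JSON or YAML) describes the physical geometry, calibration,
c0 classes, subtype selection, seeding, QC rates, dose map, ROI spec
and seeds for one run.  Unknown keys are rejected; every run echoes
its effective config to the output directory so results are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ArrayLayout, CavityGeometry, PixelCalibration
from .synth import DEFAULT_QC_RATES, SUBTYPES, DoseResponseTruth

__all__ = ["ConfigError", "ExperimentConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


_KNOWN_TOP = {
    "geometry",
    "layout",
    "calibration",
    "seeding",
    "c0",
    "qc_rates",
    "subtypes",
    "cohort",
    "dose",
    "dynamics",
    "seed",
}

_DEFAULTS = {
    "geometry": {"diameter_um": 100.0, "height_um": 200.0, "pitch_um": 600.0},
    "layout": {"rows": 25, "cols": 26},
    "calibration": {"pixel_size_um": 2.27},
    "seeding": {"mean_cells": 20.0},
    "c0": {"targets": [10, 20, 30], "tolerance": 0.10},
    "qc_rates": dict(DEFAULT_QC_RATES),
    "subtypes": ["E-9591", "Mlow-8028", "M-16992"],
    "cohort": {"n_masks_per_subtype": 20},
    "dose": {
        "concentrations_nM": [0, 10, 50, 100, 250, 500, 1000, 2500],
        "n_per_dose": 20,
        "ec50_nM": 424.5,
        "hill_coef": 1.0,
        "top": 100.0,
        "bottom": 0.0,
        "noise_cv": 0.10,
    },
    "dynamics": {"t_grid_h": list(range(2, 73, 2)), "n_replicates": 4},
    "seed": 0,
}


@dataclass
class ExperimentConfig:
    """Validated run configuration with typed accessors."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for key, default in _DEFAULTS.items():
            value = self.raw.get(key, default)
            if isinstance(default, dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                bad = set(value) - set(default)
                if bad:
                    raise ConfigError(f"unknown keys in config section {key!r}: {sorted(bad)}")
                merged[key] = {**default, **value}
            else:
                merged[key] = value
        for name in merged["subtypes"]:
            if name not in SUBTYPES:
                raise ConfigError(f"unknown subtype {name!r}; known: {sorted(SUBTYPES)}")
        self.raw = merged
        # fail fast on invalid physical parameters
        self.geometry
        self.layout
        self.calibration

    @property
    def geometry(self) -> CavityGeometry:
        return CavityGeometry(**self.raw["geometry"])

    @property
    def layout(self) -> ArrayLayout:
        return ArrayLayout(cavity=self.geometry, **self.raw["layout"])

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(**self.raw["calibration"])

    @property
    def dose_truth(self) -> DoseResponseTruth:
        d = self.raw["dose"]
        return DoseResponseTruth(
            ec50_nM=d["ec50_nM"],
            hill_coef=d["hill_coef"],
            top=d["top"],
            bottom=d["bottom"],
            noise_cv=d["noise_cv"],
        )

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def echo(self, outdir) -> Path:
        """Write the effective config next to the run's outputs."""
        out = Path(outdir) / "config_echo.json"
        out.write_text(json.dumps(self.raw, indent=2, sort_keys=True))
        return out


def load_config(path=None) -> ExperimentConfig:
    """Load a JSON/YAML config file; ``None`` yields the defaults."""
    if path is None:
        return ExperimentConfig({})
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return ExperimentConfig(data)
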