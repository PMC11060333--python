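"""Run configuration: named analysis presets plus YAML-backed overrides.

A run configuration bundles the optics of the recording, the ROI
screening thresholds, the fit options and (for the assay) the calibration
reference.  The three named presets encode the standard analysis modes:

* ``stationary_peo``   — dilute polymer solutions: ROIs start 15 px below
  the surface, 20 px tall, R^2 > 0.88;
* ``stationary_mucus`` — stationary mucus samples: same geometry,
  R^2 > 0.90;
* ``culture``          — mucus on live cultures: ROIs start 5 px below the
  surface, 3 px tall, dynamic isotropic fit range, no R^2 or outlier
  screening.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decay_fit import FitRangeRule
from .gnr_physics import OpticalConfig
from .roi_pipeline import CriteriaConfig, FitConfig, get_preset


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulate/analyze/assay run."""

    preset: str = "stationary_mucus"
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    calibration: str = "hbe_mucus"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "optics": dataclasses.asdict(self.optics),
            "criteria": dataclasses.asdict(self.criteria),
            "fit": {
                "iso_rule": self.fit.iso_rule.value,
                "hv_rule": self.fit.hv_rule.value,
                "min_points": self.fit.min_points,
                "dt_correction": self.fit.dt_correction,
                "kmax": self.fit.kmax,
            },
            "calibration": self.calibration,
            "seed": self.seed,
        }
        return d


def _build(cls, block: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {what} block: {exc}") from exc


def run_config_from_dict(data: dict) -> RunConfig:
    """Assemble a RunConfig from a plain dict (e.g. parsed YAML).

    The preset (default ``stationary_mucus``) supplies the criteria and
    fit blocks; explicit ``criteria``/``fit``/``optics`` keys override
    individual fields.
    """
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    preset = data.get("preset", "stationary_mucus")
    try:
        criteria, fit = get_preset(preset)
    except KeyError as exc:
        raise ConfigError(str(exc)) from exc
    if "criteria" in data:
        criteria = _build(
            CriteriaConfig,
            {**dataclasses.asdict(criteria), **data["criteria"]},
            "criteria",
        )
    fit_block = {
        "iso_rule": fit.iso_rule,
        "hv_rule": fit.hv_rule,
        "min_points": fit.min_points,
        "dt_correction": fit.dt_correction,
        "kmax": fit.kmax,
    }
    if "fit" in data:
        fit_block.update(data["fit"])
    try:
        fit = FitConfig(
            iso_rule=FitRangeRule(fit_block["iso_rule"]),
            hv_rule=FitRangeRule(fit_block["hv_rule"]),
            min_points=int(fit_block["min_points"]),
            dt_correction=bool(fit_block["dt_correction"]),
            kmax=fit_block["kmax"],
        )
    except ValueError as exc:
        raise ConfigError(f"invalid fit block: {exc}") from exc
    optics = _build(OpticalConfig, data.get("optics", {}), "optics")
    return RunConfig(
        preset=preset,
        optics=optics,
        criteria=criteria,
        fit=fit,
        calibration=data.get("calibration", "hbe_mucus"),
        seed=int(data.get("seed", 0)),
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return run_config_from_dict(data or {})
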