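"""YAML/JSON configuration for the model constants.

Recognised keys (all optional; defaults in parentheses):

- ``total_volume_ml`` (4.5): whole vitreous-cavity volume
- ``sea_level_pressure_kpa`` (101.325), ``lapse_rate_k_per_m`` (0.0065),
  ``sea_level_temperature_k`` (288.15), ``exponent`` (5.25588):
  barometric-formula constants
- ``anterior_chamber_ml`` (0.20): risk-ratio denominator
- ``risk_thresholds`` ([0.5, 1.0]): ascending ratio cut points
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .atmosphere import AtmosphereModel
from .errors import ConfigError
from .expansion import RiskPolicy
from .geometry import VitreousGeometry

__all__ = ["load_config", "build_models", "models_from_file"]

_KNOWN_KEYS = {
    "total_volume_ml",
    "sea_level_pressure_kpa",
    "lapse_rate_k_per_m",
    "sea_level_temperature_k",
    "exponent",
    "anterior_chamber_ml",
    "risk_thresholds",
}


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a flat dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return data


def build_models(
    config: dict | None = None,
) -> tuple[VitreousGeometry, AtmosphereModel, RiskPolicy]:
    """Instantiate geometry, atmosphere and risk-policy models from a config dict."""
    cfg = dict(config or {})
    geometry = VitreousGeometry(total_volume=cfg.get("total_volume_ml", 4.5))
    atmosphere = AtmosphereModel(
        sea_level_pressure=cfg.get("sea_level_pressure_kpa", 101.325),
        lapse_rate=cfg.get("lapse_rate_k_per_m", 0.0065),
        sea_level_temperature=cfg.get("sea_level_temperature_k", 288.15),
        exponent=cfg.get("exponent", 5.25588),
    )
    thresholds = tuple(cfg.get("risk_thresholds", (0.5, 1.0)))
    if len(thresholds) != 2:
        raise ConfigError(f"risk_thresholds must have 2 entries, got {thresholds}")
    policy = RiskPolicy(
        anterior_chamber_volume=cfg.get("anterior_chamber_ml", 0.20),
        thresholds=thresholds,  # type: ignore[arg-type]
    )
    return geometry, atmosphere, policy


def models_from_file(path=None):
    """Build models from a config file, or defaults when ``path`` is None."""
    return build_models(load_config(path) if path else None)
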