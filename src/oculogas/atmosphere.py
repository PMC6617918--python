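"""Altitude to ambient-pressure conversion (International Standard Atmosphere).

The troposphere barometric formula

    P(z) = P0 * (1 - L * z / T0) ** k,   k = g * M / (R * L) ~ 5.25588

with the ISA constants (P0 = 101.325 kPa, L = 0.0065 K/m, T0 = 288.15 K)
links a destination altitude to the ambient pressure felt by the intraocular
gas bubble. Weather-driven pressure variation is ignored: altitude is the
sole driver, and the model is valid through the troposphere
(-500 m to 11 000 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "AtmosphereModel",
    "pressure_at_altitude",
    "altitude_at_pressure",
    "kpa_to_mmhg",
    "mmhg_to_kpa",
]

#: exact conversion factor: 1 kPa in mmHg
KPA_TO_MMHG = 7.500617

ALTITUDE_MIN_M = -500.0
ALTITUDE_MAX_M = 11000.0


@dataclass(frozen=True)
class AtmosphereModel:
    """ISA troposphere pressure model; all constants configurable.

    Attributes
    ----------
    sea_level_pressure : float
        P0 in kPa (default 101.325).
    lapse_rate : float
        Temperature lapse rate L in K/m (default 0.0065).
    sea_level_temperature : float
        T0 in K (default 288.15).
    exponent : float
        g*M/(R*L), dimensionless (default 5.25588).
    """

    sea_level_pressure: float = 101.325
    lapse_rate: float = 0.0065
    sea_level_temperature: float = 288.15
    exponent: float = 5.25588

    def pressure_at_altitude(self, z: float) -> float:
        return pressure_at_altitude(self, z)

    def altitude_at_pressure(self, p: float) -> float:
        return altitude_at_pressure(self, p)


def pressure_at_altitude(model: AtmosphereModel, z: float) -> float:
    """Ambient pressure in kPa at altitude ``z`` metres.

    Raises :class:`DomainError` outside the troposphere validity range
    [-500, 11000] m.
    """
    z = float(z)
    if not (ALTITUDE_MIN_M <= z <= ALTITUDE_MAX_M) or not np.isfinite(z):
        raise DomainError(
            f"altitude must lie in [{ALTITUDE_MIN_M:.0f}, {ALTITUDE_MAX_M:.0f}] m, "
            f"got {z!r}"
        )
    base = 1.0 - model.lapse_rate * z / model.sea_level_temperature
    return model.sea_level_pressure * base**model.exponent


def altitude_at_pressure(model: AtmosphereModel, p: float) -> float:
    """Altitude in metres at which ambient pressure equals ``p`` kPa.

    Closed-form inverse of :func:`pressure_at_altitude`, accurate to well
    under 0.01 m across the validity range.
    """
    p = float(p)
    p_low = pressure_at_altitude(model, ALTITUDE_MAX_M)
    p_high = pressure_at_altitude(model, ALTITUDE_MIN_M)
    if not (p_low <= p <= p_high) or not np.isfinite(p):
        raise DomainError(
            f"pressure must lie in [{p_low:.3f}, {p_high:.3f}] kPa "
            f"(troposphere range), got {p!r}"
        )
    ratio = (p / model.sea_level_pressure) ** (1.0 / model.exponent)
    return model.sea_level_temperature / model.lapse_rate * (1.0 - ratio)


def kpa_to_mmhg(p_kpa: float) -> float:
    """Convert kPa to mmHg (1 kPa = 7.500617 mmHg)."""
    return float(p_kpa) * KPA_TO_MMHG


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert mmHg to kPa."""
    return float(p_mmhg) / KPA_TO_MMHG
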