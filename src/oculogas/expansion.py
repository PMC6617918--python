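"""Boyle's-law gas expansion and the IOP-elevation risk report.

At constant temperature a fixed amount of gas obeys P1*V1 = P2*V2. A patient
travelling from altitude z1 to a higher altitude z2 is exposed to lower
ambient pressure, so the intravitreous bubble would expand from V1 to
V2 = V1 * P1 / P2 if the eyewall did not constrain it. The unconstrained
volume increase dV = V2 - V1, scaled by the normal anterior-chamber volume,
forms the risk ratio r = dV / V_ac that drives a categorical risk report.
Eyewall compensation mechanisms (choroidal compression, scleral expansion,
aqueous outflow) are deliberately not modelled: the scenario is immediate,
direct travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .atmosphere import AtmosphereModel, pressure_at_altitude
from .errors import ConfigError, DomainError
from .geometry import VitreousGeometry, gas_volume_from_interface

__all__ = ["RiskPolicy", "ExpansionResult", "expand", "assess"]

RISK_CATEGORIES = ("none", "low", "moderate", "high")


@dataclass(frozen=True)
class RiskPolicy:
    """Maps the volume-expansion ratio to an ordered risk category.

    The anterior-chamber volume default (0.20 ml) is the typical adult
    anatomic value; the two ratio cut points delimiting low/moderate/high
    are configurable placeholders. Any non-positive expansion maps to
    "none". Cut points use a closed-left convention: a ratio exactly at a
    threshold lands in the higher category.
    """

    anterior_chamber_volume: float = 0.20
    thresholds: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if not self.anterior_chamber_volume > 0:
            raise ConfigError(
                f"anterior_chamber_volume must be positive, "
                f"got {self.anterior_chamber_volume!r}"
            )
        lo, hi = self.thresholds
        if not lo < hi:
            raise ConfigError(
                f"thresholds must be strictly ascending, got {self.thresholds!r}"
            )

    def categorize(self, risk_ratio: float) -> str:
        if risk_ratio <= 0:
            return "none"
        lo, hi = self.thresholds
        if risk_ratio >= hi:
            return "high"
        if risk_ratio >= lo:
            return "moderate"
        return "low"


@dataclass(frozen=True)
class ExpansionResult:
    """Outcome of one Boyle's-law expansion calculation.

    ``delta_v`` is signed (negative for descent); ``risk_ratio`` and
    ``category`` are set only when a :class:`RiskPolicy` was applied.
    """

    v1: float
    p1: float
    p2: float
    v2: float
    delta_v: float
    risk_ratio: Optional[float] = None
    category: Optional[str] = None
    inputs: dict = field(default_factory=dict)

    def to_report(
        self,
        geometry: Optional[VitreousGeometry] = None,
        policy: Optional[RiskPolicy] = None,
    ) -> dict:
        """JSON-serialisable risk report."""
        report = {
            "inputs": dict(self.inputs),
            "pressures_kpa": {"origin": self.p1, "destination": self.p2},
            "volumes_ml": {
                "initial_gas": self.v1,
                "expanded_gas": self.v2,
                "delta": self.delta_v,
            },
            "risk": {"ratio": self.risk_ratio, "category": self.category},
        }
        model: dict = {}
        if geometry is not None:
            model["total_volume_ml"] = geometry.total_volume
        if policy is not None:
            model["anterior_chamber_ml"] = policy.anterior_chamber_volume
            model["thresholds"] = list(policy.thresholds)
        report["model"] = model
        return report


def expand(
    v1: float, z1: float, z2: float, atmosphere: AtmosphereModel
) -> ExpansionResult:
    """Unconstrained Boyle's-law expansion of ``v1`` ml from z1 to z2 metres.

    Returns pressures at both altitudes, the expanded volume
    ``v2 = v1 * p1 / p2`` and the signed change ``delta_v = v2 - v1``;
    no risk category is attached at this level.
    """
    v1 = float(v1)
    if v1 < 0:
        raise DomainError(f"initial gas volume must be non-negative, got {v1!r}")
    p1 = pressure_at_altitude(atmosphere, z1)
    p2 = pressure_at_altitude(atmosphere, z2)
    v2 = v1 * p1 / p2
    return ExpansionResult(
        v1=v1,
        p1=p1,
        p2=p2,
        v2=v2,
        delta_v=v2 - v1,
        inputs={"origin_altitude_m": float(z1), "destination_altitude_m": float(z2)},
    )


def assess(
    h_pct: float,
    z1: float,
    z2: float,
    geometry: VitreousGeometry,
    atmosphere: AtmosphereModel,
    policy: RiskPolicy,
) -> ExpansionResult:
    """Full single-case assessment from interface height in percent.

    Composes the cavity geometry (interface height -> gas volume) with the
    Boyle's-law expansion along the route, then attaches the risk ratio
    ``delta_v / anterior_chamber_volume`` and its category. Descending or
    flat routes yield ``delta_v <= 0`` and category "none".
    """
    h_pct = float(h_pct)
    if not 0.0 <= h_pct <= 100.0:
        raise DomainError(
            f"interface height must lie in [0, 100] percent, got {h_pct!r}"
        )
    v1 = gas_volume_from_interface(geometry, h_pct / 100.0)
    base = expand(v1, z1, z2, atmosphere)
    ratio = base.delta_v / policy.anterior_chamber_volume
    return ExpansionResult(
        v1=base.v1,
        p1=base.p1,
        p2=base.p2,
        v2=base.v2,
        delta_v=base.delta_v,
        risk_ratio=ratio,
        category=policy.categorize(ratio),
        inputs={"interface_pct": h_pct, **base.inputs},
    )
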