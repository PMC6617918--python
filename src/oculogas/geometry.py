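"""Gas volume in an oblate-spheroid vitreous cavity from the fluid/gas interface height.

After vitrectomy with a gas or air tamponade, the buoyant bubble occupies the
superior part of the vitreous cavity and the fluid/gas interface is a
horizontal plane. The vertical height of the gas region, expressed as a
fraction ``h`` of the cavity's vertical extent measured downward from the
superior pole, determines the gas volume.

The cavity is idealised as an oblate spheroid of total volume 4.5 ml. Because
an axis-aligned affine scaling maps a sphere onto any such spheroid while
preserving the volume fraction of every horizontal slab versus normalised
height, the spherical-cap fraction

    f(h) = h^2 (3 - 2 h)

is exact for the spheroid regardless of its aspect ratio; only the total
volume enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "VitreousGeometry",
    "cap_volume_fraction",
    "gas_volume_from_interface",
    "interface_from_gas_volume",
]

DEFAULT_TOTAL_VOLUME_ML = 4.5


@dataclass(frozen=True)
class VitreousGeometry:
    """Oblate-spheroid vitreous cavity, parameterised by its total volume.

    Parameters
    ----------
    total_volume : float
        Whole cavity volume in ml. The adult default is 4.5 ml; eyes with
        high myopia may deviate.
    """

    total_volume: float = DEFAULT_TOTAL_VOLUME_ML

    def __post_init__(self) -> None:
        if not self.total_volume > 0:
            raise DomainError(
                f"total_volume must be positive, got {self.total_volume!r}"
            )


def _check_fraction(h: float, name: str = "h") -> float:
    h = float(h)
    if not (0.0 <= h <= 1.0) or not np.isfinite(h):
        raise DomainError(f"{name} must lie in [0, 1], got {h!r}")
    return h


def cap_volume_fraction(h: float) -> float:
    """Volume fraction of a spheroid cap of normalised height ``h``.

    ``h`` is the fill-height fraction of the vertical diameter occupied by
    gas, measured from the superior pole. Returns ``h**2 * (3 - 2*h)``,
    which is strictly increasing on [0, 1] and satisfies the equatorial
    symmetry ``f(h) + f(1-h) = 1``.
    """
    h = _check_fraction(h)
    return h * h * (3.0 - 2.0 * h)


def gas_volume_from_interface(geometry: VitreousGeometry, h: float) -> float:
    """Gas volume in ml for interface fill-height fraction ``h``."""
    return geometry.total_volume * cap_volume_fraction(h)


def interface_from_gas_volume(geometry: VitreousGeometry, volume_ml: float) -> float:
    """Fill-height fraction whose cap holds ``volume_ml`` of gas.

    Inverts :func:`gas_volume_from_interface` by bracketed root-finding on
    [0, 1]; the cubic is strictly monotone there so the root is unique.
    """
    v = float(volume_ml)
    if not (0.0 <= v <= geometry.total_volume) or not np.isfinite(v):
        raise DomainError(
            f"volume must lie in [0, {geometry.total_volume}] ml, got {v!r}"
        )
    target = v / geometry.total_volume
    if target == 0.0:
        return 0.0
    if target == 1.0:
        return 1.0
    return float(
        brentq(lambda h: h * h * (3.0 - 2.0 * h) - target, 0.0, 1.0, xtol=1e-12)
    )
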