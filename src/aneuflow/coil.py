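"""Endovascular coil as a porous medium.

A packed detachable coil of wire diameter d_w and length L_c occupies
pi*d_w^2*L_c/4 of the sac volume V_sac, so the fluid fraction (porosity) is

    eps = 1 - (pi * d_w**2 * L_c / 4) / V_sac.

The momentum sink of the coiled sac is a Darcy term -(mu/k) u applied over
the sac region.  Permeability is anchored at the two reference porosities

    eps = 0.75 -> k = 3.7e-8 m^2     (1/k = 2.70e7 1/m^2)
    eps = 0.85 -> k = 5.4e-8 m^2     (1/k = 1.85e7 1/m^2)

and interpolated/extrapolated linearly in eps between/beyond them; eps = 1
means "no coil" and disables the sink entirely (infinite permeability).
No Forchheimer (quadratic) resistance is included: only permeabilities are
specified for the reference coils, and the sac-interior velocities are
small.  A quadratic coefficient slot exists in the case config, default 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CoilSpec", "PorousProps", "porosity_from_coil",
           "permeability_for_porosity", "props_for_porosity", "darcy_sink",
           "TABLE_POROSITIES", "TABLE_PERMEABILITIES"]

TABLE_POROSITIES = (0.75, 0.85)
TABLE_PERMEABILITIES = (3.7e-8, 5.4e-8)  # m^2
_K_FLOOR = 1e-14  # m^2, keeps extrapolation physical for very tight packing


@dataclass(frozen=True)
class CoilSpec:
    """Coil wire geometry and the sac volume it packs into (SI units)."""

    wire_diameter: float  # m
    length: float         # m
    sac_volume: float     # m^3

    def __post_init__(self):
        for name in ("wire_diameter", "length", "sac_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wire_volume >= self.sac_volume:
            raise ValueError("coil volume exceeds sac volume (overpacked)")

    @property
    def wire_volume(self) -> float:
        return math.pi * self.wire_diameter ** 2 * self.length / 4.0


@dataclass(frozen=True)
class PorousProps:
    """Porosity and Darcy permeability of the coiled sac; eps = 1 <=> uncoiled."""

    porosity: float
    permeability: float  # m^2; +inf disables the sink

    def __post_init__(self):
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must lie in (0, 1]")
        if not self.permeability > 0:
            raise ValueError("permeability must be positive")

    @property
    def enabled(self) -> bool:
        return math.isfinite(self.permeability)


def porosity_from_coil(spec: CoilSpec) -> float:
    """Fluid volume fraction of the sac once the coil is packed in."""
    return 1.0 - spec.wire_volume / spec.sac_volume


def permeability_for_porosity(eps: float) -> float:
    """Darcy permeability (m^2) for porosity ``eps``.

    Linear in eps through the two reference points; ``eps == 1`` returns
    +inf (sink disabled).  Clamped to a small positive floor.
    """
    if eps <= 0 or eps > 1:
        raise ValueError(f"porosity must lie in (0, 1], got {eps}")
    if eps == 1.0:
        return math.inf
    (e0, e1), (k0, k1) = TABLE_POROSITIES, TABLE_PERMEABILITIES
    k = k0 + (eps - e0) * (k1 - k0) / (e1 - e0)
    return max(k, _K_FLOOR)


def props_for_porosity(eps: float, permeability: float | None = None) -> PorousProps:
    """Bundle porosity with its (table or explicit) permeability."""
    if permeability is None:
        permeability = permeability_for_porosity(eps)
    return PorousProps(porosity=eps, permeability=permeability)


def darcy_sink(u, mu_app, props: PorousProps):
    """Pointwise Darcy momentum sink -(mu/k) u, in Pa/m per unit volume.

    The solver applies this only over sac-tagged cells; with eps = 1 the
    coefficient is exactly zero so an uncoiled run is bit-identical to a run
    with the porous model absent.
    """
    u = np.asarray(u, dtype=float)
    if not props.enabled:
        return np.zeros_like(u)
    return -(np.asarray(mu_app, dtype=float) / props.permeability) * u
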