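"""Immersion-fluid specifications and water-density constants.

All densities are in g·cm⁻³ at 22–23 °C, the operating temperature of the
resonator measurements this package models.  Masses are femtograms and
volumes femtolitres throughout the package; the unit system is internally
consistent (1 fg/fL = 1 g·cm⁻³) so no conversion factors appear anywhere.

A fluid is described by its bulk density, whether the cell membrane is
permeable to it (water-based fluids exchange with intracellular water;
iodixanol-based fluids do not), and the density the cell's exchangeable
water assumes once equilibrated with it — pure-H₂O density in an H₂O-based
fluid, the heavy-water mixture density in a D₂O-based one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Density of pure H2O at 22-23 degC, g/cm^3.
RHO_H2O = 0.9975

#: Density of pure D2O at 22-23 degC, g/cm^3.
RHO_D2O = 1.1040


def heavy_water_mixture_density(
    d2o_volume_fraction: float,
    rho_h2o: float = RHO_H2O,
    rho_d2o: float = RHO_D2O,
) -> float:
    """Density of a D2O:H2O mixture by ideal volume mixing.

    Parameters
    ----------
    d2o_volume_fraction
        Volume fraction of D2O in [0, 1] (0.9 for the standard 9:1 v/v
        D2O:H2O measurement fluid).
    """
    f = float(d2o_volume_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"d2o_volume_fraction must be in [0, 1], got {f}")
    return f * rho_d2o + (1.0 - f) * rho_h2o


#: Density of the standard 9:1 v/v D2O:H2O mixture, g/cm^3.
RHO_D2O_9TO1 = heavy_water_mixture_density(0.9)


@dataclass(frozen=True)
class FluidSpec:
    """An immersion fluid for buoyant-mass measurements.

    Attributes
    ----------
    label
        Human-readable identifier, used as the pairing key in tables.
    density
        Bulk fluid density in g/cm^3.
    permeable
        True if the fluid's water exchanges across the cell membrane.
    intracellular_water_density
        Density (g/cm^3) the cell's exchangeable water takes once
        equilibrated with this fluid.  For an impermeable fluid the water
        keeps its native density and this field records that value.
    """

    label: str
    density: float
    permeable: bool
    intracellular_water_density: float

    def __post_init__(self) -> None:
        for name in ("density", "intracellular_water_density"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "density": self.density,
            "permeable": self.permeable,
            "intracellular_water_density": self.intracellular_water_density,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FluidSpec":
        return cls(
            label=str(d["label"]),
            density=float(d["density"]),
            permeable=bool(d["permeable"]),
            intracellular_water_density=float(d["intracellular_water_density"]),
        )


def standard_fluids() -> dict[str, FluidSpec]:
    """The measurement fluids used throughout the package.

    ``pbs_h2o`` / ``pbs_d2o`` are the isotonic 1x PBS fluids (densities
    1.005 and 1.101 g/cm^3) in which cells are actually weighed; their
    intracellular-water densities are the pure-fluid values, so the water
    term is *not* exactly neutrally buoyant in them — this small departure
    is what the systematic-bias module quantifies.  ``h2o`` / ``d2o_9to1``
    are the pure fluids where water is exactly neutral, and
    ``optiprep_pbs`` is the dense impermeable iodixanol fluid used for
    water-content measurements.
    """
    return {
        "h2o": FluidSpec("h2o", RHO_H2O, True, RHO_H2O),
        "d2o_9to1": FluidSpec("d2o_9to1", RHO_D2O_9TO1, True, RHO_D2O_9TO1),
        "pbs_h2o": FluidSpec("pbs_h2o", 1.005, True, RHO_H2O),
        "pbs_d2o": FluidSpec("pbs_d2o", 1.101, True, RHO_D2O_9TO1),
        "optiprep_pbs": FluidSpec("optiprep_pbs", 1.101, False, RHO_H2O),
    }
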