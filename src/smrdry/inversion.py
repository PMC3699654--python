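"""Forward buoyant-mass model and closed-form dual-fluid inversions.

A suspended microchannel resonator (SMR) weighs one cell at a time,
returning its buoyant mass

    m_b = m - V * rho_f,

the cell's mass minus the mass of fluid it displaces.  Splitting the cell
into dry material (mass ``m_dry``, density ``rho_dry``) and exchangeable
water (volume ``V_w``, density ``rho_w``) decomposes this into

    m_b = m_dry * (1 - rho_f / rho_dry) + V_w * (rho_w - rho_f).

Weighing the same cell sequentially in an H2O-based and a D2O-based fluid,
with intracellular water rapidly exchanging so that it is neutrally buoyant
in both, leaves only the dry term, and the pair (m_b1, m_b2) determines dry
mass, dry volume and dry density in closed form.  Pairing a dense
impermeable fluid with a density-matched D2O-based fluid instead isolates
the water content, and a pair of impermeable fluids recovers the cell's
total mass, volume and density.

Units are fg, fL and g·cm⁻³ (1 fg/fL = 1 g·cm⁻³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, MatchedDensityError
from .fluids import RHO_H2O, FluidSpec

__all__ = [
    "CellSpec",
    "MeasurementPair",
    "DryResult",
    "WaterResult",
    "TotalResult",
    "forward_buoyant_mass",
    "solve_dry",
    "solve_water",
    "solve_total",
    "percent_dry",
    "invert_dry_arrays",
]


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth composition of a cell for the forward model.

    Attributes
    ----------
    dry_mass
        Mass of non-aqueous material, fg.
    dry_density
        Density of the dry material, g/cm^3.
    water_volume
        Volume of exchangeable intracellular water, fL.
    water_density
        Native density of that water, g/cm^3 (pure H2O by default).
    """

    dry_mass: float
    dry_density: float
    water_volume: float = 0.0
    water_density: float = RHO_H2O

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dry_mass) and self.dry_mass >= 0):
            raise ValueError(f"dry_mass must be finite and >= 0, got {self.dry_mass!r}")
        if not (math.isfinite(self.dry_density) and self.dry_density > 0):
            raise ValueError(f"dry_density must be finite and > 0, got {self.dry_density!r}")
        if not (math.isfinite(self.water_volume) and self.water_volume >= 0):
            raise ValueError(f"water_volume must be finite and >= 0, got {self.water_volume!r}")
        if not (math.isfinite(self.water_density) and self.water_density > 0):
            raise ValueError(f"water_density must be finite and > 0, got {self.water_density!r}")

    @property
    def dry_volume(self) -> float:
        """Volume of the dry material, fL."""
        return self.dry_mass / self.dry_density

    @property
    def total_mass(self) -> float:
        """Dry mass plus water mass, fg."""
        return self.dry_mass + self.water_volume * self.water_density

    @property
    def total_volume(self) -> float:
        """Dry volume plus water volume, fL."""
        return self.dry_volume + self.water_volume


@dataclass(frozen=True)
class MeasurementPair:
    """Two buoyant masses of one cell in two specified fluids."""

    cell_id: str
    mb1: float
    fluid1: FluidSpec
    mb2: float
    fluid2: FluidSpec
    exposure_time: float | None = None  # seconds in the second fluid

    def __post_init__(self) -> None:
        for name in ("mb1", "mb2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class DryResult:
    """Dry-composition inversion output.

    ``valid`` is False when the inferred dry volume is non-positive (noise
    can push small cells across zero); the numbers are still reported so
    that downstream filtering is explicit.
    """

    dry_mass: float  # fg
    dry_volume: float  # fL
    dry_density: float  # g/cm^3, nan when dry_volume == 0
    valid: bool


@dataclass(frozen=True)
class WaterResult:
    water_mass: float  # fg
    water_volume: float  # fL


@dataclass(frozen=True)
class TotalResult:
    total_mass: float  # fg
    total_volume: float  # fL
    total_density: float  # g/cm^3
    valid: bool = True


def forward_buoyant_mass(
    cell: CellSpec,
    fluid: FluidSpec,
    residual_h2o_fraction: float | None = None,
) -> float:
    """Buoyant mass of ``cell`` immersed in ``fluid``, fg.

    ``residual_h2o_fraction`` is the fraction of intracellular water that
    has *not yet* exchanged with the fluid: 1 means the water keeps its
    native density, 0 means it has fully equilibrated to
    ``fluid.intracellular_water_density``.  Defaults to full equilibration
    for permeable fluids; impermeable fluids cannot exchange and force 1.
    """
    if residual_h2o_fraction is None:
        residual_h2o_fraction = 0.0 if fluid.permeable else 1.0
    f = float(residual_h2o_fraction)
    if not (math.isfinite(f) and 0.0 <= f <= 1.0):
        raise ValueError(f"residual_h2o_fraction must be in [0, 1], got {f!r}")
    if not fluid.permeable:
        f = 1.0
    rho_w_eff = f * cell.water_density + (1.0 - f) * fluid.intracellular_water_density
    dry_term = cell.dry_mass * (1.0 - fluid.density / cell.dry_density)
    water_term = cell.water_volume * (rho_w_eff - fluid.density)
    return dry_term + water_term


def invert_dry_arrays(
    mb1: np.ndarray | float,
    mb2: np.ndarray | float,
    rho1: float,
    rho2: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-fluid inversion: (mass, volume, density) arrays.

    mass = (mb1*rho2 - mb2*rho1) / (rho2 - rho1)
    volume = (mb1 - mb2) / (rho2 - rho1)
    density = mass / volume (nan where volume == 0)

    Valid for both the dry inversion (permeable fluids, water neutrally
    buoyant) and the total inversion (impermeable fluids).
    """
    if rho1 == rho2:
        raise DegenerateInputError(
            f"fluid densities must differ, both are {rho1} g/cm^3"
        )
    mb1 = np.asarray(mb1, dtype=float)
    mb2 = np.asarray(mb2, dtype=float)
    drho = rho2 - rho1
    mass = (mb1 * rho2 - mb2 * rho1) / drho
    volume = (mb1 - mb2) / drho
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(volume != 0.0, mass / np.where(volume != 0.0, volume, 1.0), np.nan)
    return mass, volume, density


def _check_distinct(fluid1: FluidSpec, fluid2: FluidSpec) -> None:
    if fluid1.density == fluid2.density:
        raise DegenerateInputError(
            f"fluids {fluid1.label!r} and {fluid2.label!r} have equal density "
            f"{fluid1.density}; the inversion is degenerate"
        )


def solve_dry(pair: MeasurementPair) -> DryResult:
    """Dry mass, dry volume and dry density from a permeable-fluid pair.

    Assumes intracellular water fully exchanged and neutrally buoyant in
    both fluids, so the water term of the buoyant-mass decomposition
    vanishes and the dry quantities follow in closed form.
    """
    if not (pair.fluid1.permeable and pair.fluid2.permeable):
        raise DegenerateInputError(
            "dry inversion requires two water-permeable fluids; got "
            f"{pair.fluid1.label!r} (permeable={pair.fluid1.permeable}) and "
            f"{pair.fluid2.label!r} (permeable={pair.fluid2.permeable})"
        )
    _check_distinct(pair.fluid1, pair.fluid2)
    mass, vol, dens = invert_dry_arrays(
        pair.mb1, pair.mb2, pair.fluid1.density, pair.fluid2.density
    )
    valid = bool(vol > 0) and bool(np.isfinite(dens))
    return DryResult(float(mass), float(vol), float(dens), valid)


def solve_water(
    pair: MeasurementPair,
    water_density: float = RHO_H2O,
    density_tolerance: float = 0.001,
) -> WaterResult:
    """Water mass and volume from an impermeable/permeable fluid pair.

    The first fluid must be impermeable (e.g. iodixanol-based) and the
    second permeable (D2O-based), with their densities matched to within
    ``density_tolerance`` so that the dry term cancels in the difference.
    The difference mb1 - mb2 is then the buoyant mass of the intracellular
    water in the impermeable fluid, V_w * (rho_w - rho_f).
    """
    if pair.fluid1.permeable or not pair.fluid2.permeable:
        raise DegenerateInputError(
            "water inversion requires an impermeable first fluid and a "
            f"permeable second fluid; got {pair.fluid1.label!r} "
            f"(permeable={pair.fluid1.permeable}) and {pair.fluid2.label!r} "
            f"(permeable={pair.fluid2.permeable})"
        )
    rho_f = pair.fluid1.density
    mismatch = abs(rho_f - pair.fluid2.density)
    if mismatch > density_tolerance:
        raise MatchedDensityError(
            f"fluid densities differ by {mismatch:.4g} g/cm^3, more than the "
            f"matched-density tolerance {density_tolerance:g}"
        )
    if rho_f == water_density:
        raise DegenerateInputError(
            f"fluid density equals the water density {water_density}; the "
            "water signal vanishes"
        )
    water_volume = (pair.mb2 - pair.mb1) / (rho_f - water_density)
    return WaterResult(water_mass=water_volume * water_density, water_volume=water_volume)


def solve_total(pair: MeasurementPair) -> TotalResult:
    """Total mass, volume and density from two impermeable fluids.

    With no water exchange the whole cell behaves as a single particle and
    the same two-fluid algebra as the dry inversion applies to its totals.
    """
    if pair.fluid1.permeable or pair.fluid2.permeable:
        raise DegenerateInputError(
            "total inversion requires two impermeable fluids; got "
            f"{pair.fluid1.label!r} (permeable={pair.fluid1.permeable}) and "
            f"{pair.fluid2.label!r} (permeable={pair.fluid2.permeable})"
        )
    _check_distinct(pair.fluid1, pair.fluid2)
    mass, vol, dens = invert_dry_arrays(
        pair.mb1, pair.mb2, pair.fluid1.density, pair.fluid2.density
    )
    valid = bool(vol > 0) and bool(np.isfinite(dens))
    return TotalResult(float(mass), float(vol), float(dens), valid)


def percent_dry(
    dry_mass: float,
    total_mass: float,
    dry_volume: float,
    water_volume: float,
) -> tuple[float, float]:
    """Percent dry material by mass and by volume.

    Returns (100*dry_mass/total_mass, 100*dry_volume/(dry_volume+water_volume)).
    """
    if total_mass <= 0:
        raise DegenerateInputError(f"total_mass must be > 0, got {total_mass!r}")
    total_volume = dry_volume + water_volume
    if total_volume <= 0:
        raise DegenerateInputError(
            f"dry_volume + water_volume must be > 0, got {total_volume!r}"
        )
    return 100.0 * dry_mass / total_mass, 100.0 * dry_volume / total_volume


@dataclass
class _PairColumns:
    """Column names for table-level inversion (internal)."""

    mb1: str = "mb1_fg"
    mb2: str = "mb2_fg"


def invert_dry_table(pairs, fluid1: FluidSpec, fluid2: FluidSpec):
    """Dry inversion applied to a pairs DataFrame.

    ``pairs`` needs columns ``cell_id``, ``mb1_fg``, ``mb2_fg`` and may
    carry ``exposure_time_s``.  Returns a DataFrame with per-cell dry mass,
    volume, density and a validity flag.
    """
    import pandas as pd

    if not (fluid1.permeable and fluid2.permeable):
        raise DegenerateInputError("dry inversion requires two permeable fluids")
    mass, vol, dens = invert_dry_arrays(
        pairs["mb1_fg"].to_numpy(), pairs["mb2_fg"].to_numpy(),
        fluid1.density, fluid2.density,
    )
    out = pd.DataFrame(
        {
            "cell_id": pairs["cell_id"].to_numpy(),
            "dry_mass_fg": mass,
            "dry_volume_fL": vol,
            "dry_density_g_per_cm3": dens,
            "valid": (vol > 0) & np.isfinite(dens),
        }
    )
    if "exposure_time_s" in pairs.columns:
        out["exposure_time_s"] = pairs["exposure_time_s"].to_numpy()
    return out
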