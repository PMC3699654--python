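"""Systematic dry-density error sources.

Two systematic effects can bias the dry-density estimate:

1. **Non-pure measurement fluids.**  Isotonic (PBS-based) fluids are denser
   than the pure H2O / 9:1 D2O:H2O they are built on, while the cell's
   exchangeable water equilibrates to the *pure-fluid* densities.  The
   water term of the buoyant-mass decomposition is then not exactly zero,
   and the closed-form inversion — which assumes it is — picks up a bias
   that grows with the cell's water fraction.  For equal density departures
   delta in both fluids the volume bias cancels exactly and the density
   bias is exactly ``-delta * V_w / V_dry``.

2. **Incomplete water exchange.**  If intracellular H2O has not fully
   exchanged for D2O by the time of the second weighing, early-exposure
   cells report depressed dry densities.  This is tested by ordinary
   least-squares regression of per-cell dry density on exposure time with
   a one-sided t-test (slope > 0 under residual-H2O decay), Bonferroni
   corrected across the batch of analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError
from .fluids import FluidSpec
from .inversion import CellSpec, MeasurementPair, forward_buoyant_mass, solve_dry

__all__ = [
    "BiasMap",
    "ExposureRegressionResult",
    "dry_density_bias",
    "bias_map",
    "exposure_time_regression",
]


def dry_density_bias(
    true_cell: CellSpec,
    fluid1: FluidSpec,
    fluid2: FluidSpec,
) -> float:
    """Estimated minus true dry density when water is not exactly neutral.

    The forward model is evaluated with the water term included (water at
    each fluid's ``intracellular_water_density``, fully exchanged), then
    inverted with :func:`~smrdry.inversion.solve_dry`, which assumes the
    water term is zero.  The returned bias is zero exactly when each
    fluid's density equals its intracellular-water density.
    """
    if not (fluid1.permeable and fluid2.permeable):
        raise DegenerateInputError("bias analysis applies to permeable fluid pairs")
    if fluid1.density == fluid2.density:
        raise DegenerateInputError("degenerate fluid pair: equal densities")
    mb1 = forward_buoyant_mass(true_cell, fluid1, residual_h2o_fraction=0.0)
    mb2 = forward_buoyant_mass(true_cell, fluid2, residual_h2o_fraction=0.0)
    est = solve_dry(MeasurementPair("bias", mb1, fluid1, mb2, fluid2))
    return est.dry_density - true_cell.dry_density


@dataclass(frozen=True)
class BiasMap:
    """Dry-density bias on a (water fraction) x (density departure) grid.

    ``bias[i, j]`` is the estimated-minus-true dry density for a cell with
    water fraction ``water_fractions[i]`` measured in fluids whose
    densities exceed the pure-fluid baselines by ``departures1[j]`` and
    ``departures2[j]`` respectively.
    """

    water_fractions: np.ndarray  # fraction of total volume
    departures1: np.ndarray  # g/cm^3 added to fluid 1 beyond pure baseline
    departures2: np.ndarray  # g/cm^3 added to fluid 2 beyond pure baseline
    bias: np.ndarray  # g/cm^3, shape (n_wf, n_dep)
    reference_cell_density: float
    operating_point: tuple[float, float] | None = None  # e.g. the 1x PBS departures


def bias_map(
    water_fractions,
    departures1,
    departures2,
    reference_cell_density: float = 1.4,
    pure_fluid1: FluidSpec | None = None,
    pure_fluid2: FluidSpec | None = None,
    operating_point: tuple[float, float] | None = None,
) -> BiasMap:
    """Evaluate :func:`dry_density_bias` over a grid.

    ``departures1`` and ``departures2`` are paired element-wise (one
    departure axis applied per fluid); ``water_fractions`` are fractions of
    total cell volume in [0, 0.99].  Pure baselines default to pure H2O and
    9:1 D2O:H2O; intracellular water keeps the pure-fluid densities while
    the fluid densities carry the departures.
    """
    from .fluids import RHO_D2O_9TO1, RHO_H2O

    wf = np.asarray(water_fractions, dtype=float)
    d1 = np.asarray(departures1, dtype=float)
    d2 = np.asarray(departures2, dtype=float)
    if wf.size == 0 or d1.size == 0:
        raise ValueError("grids must be non-empty")
    if d1.shape != d2.shape:
        raise ValueError("departures1 and departures2 must have equal length")
    if np.any((wf < 0) | (wf > 0.99)):
        raise ValueError("water fractions must lie in [0, 0.99]")
    if pure_fluid1 is None:
        pure_fluid1 = FluidSpec("h2o", RHO_H2O, True, RHO_H2O)
    if pure_fluid2 is None:
        pure_fluid2 = FluidSpec("d2o_9to1", RHO_D2O_9TO1, True, RHO_D2O_9TO1)

    bias = np.empty((wf.size, d1.size), dtype=float)
    for i, w in enumerate(wf):
        # Unit dry volume; water volume set by the requested total-volume fraction.
        v_w = w / (1.0 - w)
        cell = CellSpec(
            dry_mass=reference_cell_density,
            dry_density=reference_cell_density,
            water_volume=v_w,
            water_density=pure_fluid1.intracellular_water_density,
        )
        for j, (dep1, dep2) in enumerate(zip(d1, d2)):
            f1 = FluidSpec(
                pure_fluid1.label, pure_fluid1.density + dep1, True,
                pure_fluid1.intracellular_water_density,
            )
            f2 = FluidSpec(
                pure_fluid2.label, pure_fluid2.density + dep2, True,
                pure_fluid2.intracellular_water_density,
            )
            bias[i, j] = dry_density_bias(cell, f1, f2)
    return BiasMap(
        water_fractions=wf,
        departures1=d1,
        departures2=d2,
        bias=bias,
        reference_cell_density=float(reference_cell_density),
        operating_point=operating_point,
    )


@dataclass(frozen=True)
class ExposureRegressionResult:
    """OLS of dry density on exposure time, one-sided slope test."""

    slope: float  # g/cm^3 per s
    intercept: float
    p_value_one_sided: float
    corrected_alpha: float
    significant: bool
    r_squared: float
    n: int
    direction: str  # "greater" or "less"


def exposure_time_regression(
    exposure_times,
    dry_densities,
    n_tests_for_bonferroni: int = 1,
    direction: str = "greater",
    alpha: float = 0.05,
) -> ExposureRegressionResult:
    """Test for residual (incomplete) water exchange.

    Ordinary least squares of per-cell dry density on time spent in the
    second (D2O-based) fluid.  Under incomplete exchange, retained H2O
    depresses early-exposure density estimates, so the predicted
    alternative is slope > 0 (``direction="greater"``, the default).  The
    per-test significance level is Bonferroni-corrected:
    ``corrected_alpha = alpha / n_tests_for_bonferroni``.
    """
    t = np.asarray(exposure_times, dtype=float)
    y = np.asarray(dry_densities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("exposure_times and dry_densities must be equal-length 1-D")
    if t.size < 3:
        raise DegenerateInputError(
            f"need >= 3 points for a slope t-test, got {t.size}"
        )
    if np.unique(t).size < 2:
        raise DegenerateInputError("all exposure times are equal; slope is undefined")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if n_tests_for_bonferroni < 1:
        raise ValueError("n_tests_for_bonferroni must be >= 1")

    res = sm.OLS(y, sm.add_constant(t)).fit()
    slope = float(res.params[1])
    tval = float(res.tvalues[1])
    df = int(res.df_resid)
    if direction == "greater":
        p = float(stats.t.sf(tval, df))
    else:
        p = float(stats.t.cdf(tval, df))
    corrected = alpha / n_tests_for_bonferroni
    return ExposureRegressionResult(
        slope=slope,
        intercept=float(res.params[0]),
        p_value_one_sided=p,
        corrected_alpha=corrected,
        significant=bool(p < corrected),
        r_squared=float(res.rsquared),
        n=int(t.size),
        direction=direction,
    )
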