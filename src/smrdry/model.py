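"""Model/Results surface tying the pipeline together.

``DryCompositionModel`` is constructed from paired buoyant-mass data and a
fluid pair; ``fit()`` runs the closed-form inversion per cell and returns a
``DryCompositionResults`` carrying per-cell estimates, population medians
with bootstrap standard errors, the analytic error-amplification factor,
the Monte-Carlo noise-only density null (when an error model is supplied)
and the exposure-time exchange diagnostic (when exposure times are
present), with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import ExposureRegressionResult, exposure_time_regression
from .errors import DegenerateInputError
from .fluids import FluidSpec
from .inversion import invert_dry_table
from .io import pair_measurements
from .noise import (
    ErrorModel,
    NullDensityDistribution,
    compare_to_null,
    dry_mass_error_factor,
    simulate_null_density,
)
from .popstats import median_summary

__all__ = ["DryCompositionModel", "DryCompositionResults"]


class DryCompositionModel:
    """Dry-composition estimation from paired buoyant-mass measurements.

    Parameters
    ----------
    pairs
        DataFrame with ``cell_id``, ``mb1_fg``, ``mb2_fg`` and optionally
        ``exposure_time_s``.
    fluid1, fluid2
        The water-permeable measurement fluids (H2O-based then D2O-based).
    error_model
        Optional single-measurement error model from repeat pairs; enables
        the noise-only null distribution in the fitted results.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        fluid1: FluidSpec,
        fluid2: FluidSpec,
        error_model: ErrorModel | None = None,
    ) -> None:
        required = {"cell_id", "mb1_fg", "mb2_fg"}
        missing = required - set(pairs.columns)
        if missing:
            raise DegenerateInputError(f"pairs table missing columns {sorted(missing)}")
        if len(pairs) == 0:
            raise DegenerateInputError("pairs table is empty")
        self.pairs = pairs.reset_index(drop=True)
        self.fluid1 = fluid1
        self.fluid2 = fluid2
        self.error_model = error_model

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        fluids: dict[str, FluidSpec],
        fluid1_label: str,
        fluid2_label: str,
        error_model: ErrorModel | None = None,
        pairing_policy: str = "strict",
    ) -> "DryCompositionModel":
        """Build from a long-format measurement table plus a fluid table."""
        for label in (fluid1_label, fluid2_label):
            if label not in fluids:
                raise KeyError(f"fluid {label!r} not in fluid table {sorted(fluids)}")
        pairs, report = pair_measurements(records, fluid1_label, fluid2_label, pairing_policy)
        model = cls(pairs, fluids[fluid1_label], fluids[fluid2_label], error_model)
        model.pairing_report = report
        return model

    def fit(
        self,
        n_boot: int = 1000,
        n_sim: int = 10_000,
        seed: int = 0,
    ) -> "DryCompositionResults":
        """Run the inversion and population summaries."""
        cells = invert_dry_table(self.pairs, self.fluid1, self.fluid2)
        valid = cells[cells["valid"]]
        if len(valid) == 0:
            raise DegenerateInputError("no cell yielded a valid (positive) dry volume")

        med_mass, se_mass = median_summary(valid["dry_mass_fg"], n_boot, seed)
        med_vol, se_vol = median_summary(valid["dry_volume_fL"], n_boot, seed + 1)
        med_dens, se_dens = median_summary(valid["dry_density_g_per_cm3"], n_boot, seed + 2)

        null = None
        null_comparison = None
        if self.error_model is not None:
            null = simulate_null_density(
                valid["dry_mass_fg"].to_numpy(),
                med_dens,
                (self.fluid1, self.fluid2),
                self.error_model,
                n_sim=n_sim,
                seed=seed + 3,
            )
            null_comparison = compare_to_null(
                valid["dry_density_g_per_cm3"].to_numpy(), null
            )

        exposure_reg = None
        if "exposure_time_s" in cells.columns:
            sub = valid.dropna(subset=["exposure_time_s"])
            if len(sub) >= 3 and sub["exposure_time_s"].nunique() >= 2:
                exposure_reg = exposure_time_regression(
                    sub["exposure_time_s"], sub["dry_density_g_per_cm3"]
                )

        return DryCompositionResults(
            model=self,
            cells=cells,
            median_dry_mass=med_mass,
            se_dry_mass=se_mass,
            median_dry_volume=med_vol,
            se_dry_volume=se_vol,
            median_dry_density=med_dens,
            se_dry_density=se_dens,
            error_factor=dry_mass_error_factor(self.fluid1.density, self.fluid2.density),
            null=null,
            null_comparison=null_comparison,
            exposure_regression=exposure_reg,
            seed=seed,
        )


@dataclass
class DryCompositionResults:
    """Fitted dry-composition estimates and diagnostics."""

    model: DryCompositionModel
    cells: pd.DataFrame  # per-cell inversion output
    median_dry_mass: float
    se_dry_mass: float
    median_dry_volume: float
    se_dry_volume: float
    median_dry_density: float
    se_dry_density: float
    error_factor: float
    null: NullDensityDistribution | None = None
    null_comparison: dict | None = None
    exposure_regression: ExposureRegressionResult | None = None
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_valid(self) -> int:
        return int(self.cells["valid"].sum())

    def summary(self) -> str:
        """Human-readable summary table."""
        f1, f2 = self.model.fluid1, self.model.fluid2
        lines = [
            "Dry composition from paired buoyant-mass measurements",
            "=" * 56,
            f"fluids: {f1.label} (rho={f1.density:.4f}) / {f2.label} (rho={f2.density:.4f}) g/cm^3",
            f"cells: {self.n_cells} measured, {self.n_valid} valid",
            f"median dry mass:    {self.median_dry_mass:10.2f} +/- {self.se_dry_mass:.2f} fg",
            f"median dry volume:  {self.median_dry_volume:10.2f} +/- {self.se_dry_volume:.2f} fL",
            f"median dry density: {self.median_dry_density:10.4f} +/- {self.se_dry_density:.4f} g/cm^3",
            f"dry-mass error amplification: {self.error_factor:.1f}x single-measurement error",
        ]
        if self.null is not None:
            lo, hi = self.null.bounds_99
            lines.append(
                f"noise-only 99% density bounds: [{lo:.4f}, {hi:.4f}] g/cm^3 "
                f"(n_sim={self.null.n_sim})"
            )
            if self.null_comparison is not None:
                lines.append(
                    "observed fraction outside bounds: "
                    f"{self.null_comparison['exceedance_fraction']:.3f}"
                )
        if self.exposure_regression is not None:
            r = self.exposure_regression
            lines.append(
                f"exposure-time slope: {r.slope:+.3e} g/cm^3/s "
                f"(one-sided p={r.p_value_one_sided:.3g}, "
                f"{'significant' if r.significant else 'not significant'} "
                f"at alpha={r.corrected_alpha:.4g})"
            )
        return "\n".join(lines)
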