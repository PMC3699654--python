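"""Delimited-text readers/writers, pairing, and run manifests.

Schemas (CSV with header, densities carried at full precision):

- measurements: ``cell_id,fluid_label,buoyant_mass_fg,exposure_time_s``
  (exposure may be empty on first-fluid records)
- fluids: ``label,density_g_per_cm3,permeable,intracellular_water_density_g_per_cm3``
- repeat pairs: ``cell_id,mb_a_fg,mb_b_fg``
- calibration: ``peak_height_hz,buoyant_mass_fg`` / ``baseline_freq_hz,density_g_per_cm3``

Schema violations raise :class:`~smrdry.errors.SchemaError` naming the
offending row and column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fluids import FluidSpec

__all__ = [
    "MEASUREMENT_COLUMNS",
    "FLUID_COLUMNS",
    "read_measurements",
    "read_fluids",
    "write_results",
    "pair_measurements",
    "RunManifest",
]

MEASUREMENT_COLUMNS = ["cell_id", "fluid_label", "buoyant_mass_fg", "exposure_time_s"]
FLUID_COLUMNS = [
    "label",
    "density_g_per_cm3",
    "permeable",
    "intracellular_water_density_g_per_cm3",
]
SCHEMA_VERSION = "1"


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}; expected {expected}")
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; expected {expected}")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a buoyant-mass measurement table."""
    df = pd.read_csv(path)
    _check_columns(df, MEASUREMENT_COLUMNS, path)
    bm = pd.to_numeric(df["buoyant_mass_fg"], errors="coerce")
    bad = ~np.isfinite(bm.to_numpy(dtype=float))
    if bad.any():
        row = int(np.argmax(bad))
        raise SchemaError(
            f"{path}: non-finite buoyant_mass_fg at row {row} "
            f"(value {df['buoyant_mass_fg'].iloc[row]!r})"
        )
    df["buoyant_mass_fg"] = bm
    df["exposure_time_s"] = pd.to_numeric(df["exposure_time_s"], errors="coerce")
    df["cell_id"] = df["cell_id"].astype(str)
    df["fluid_label"] = df["fluid_label"].astype(str)
    return df


def read_fluids(path) -> dict[str, FluidSpec]:
    """Read a fluid table into a label -> FluidSpec mapping."""
    df = pd.read_csv(path)
    _check_columns(df, FLUID_COLUMNS, path)
    fluids: dict[str, FluidSpec] = {}
    for i, row in df.iterrows():
        for col in ("density_g_per_cm3", "intracellular_water_density_g_per_cm3"):
            v = float(row[col])
            if not (np.isfinite(v) and v > 0):
                raise SchemaError(f"{path}: row {i}, column {col}: invalid density {row[col]!r}")
        fluids[str(row["label"])] = FluidSpec(
            label=str(row["label"]),
            density=float(row["density_g_per_cm3"]),
            permeable=bool(row["permeable"]),
            intracellular_water_density=float(row["intracellular_water_density_g_per_cm3"]),
        )
    return fluids


def write_fluids(path, fluids: dict[str, FluidSpec]) -> None:
    pd.DataFrame(
        [
            {
                "label": f.label,
                "density_g_per_cm3": f.density,
                "permeable": f.permeable,
                "intracellular_water_density_g_per_cm3": f.intracellular_water_density,
            }
            for f in fluids.values()
        ]
    ).to_csv(path, index=False)


def write_results(path, table: pd.DataFrame) -> None:
    """Write a result table as CSV (no index column)."""
    table.to_csv(path, index=False)


def pair_measurements(
    records: pd.DataFrame,
    fluid1_label: str,
    fluid2_label: str,
    pairing_policy: str = "strict",
) -> tuple[pd.DataFrame, dict]:
    """Pair per-cell records from two fluids into (mb1, mb2) rows.

    Under the default ``strict`` policy each cell must have exactly one
    record per fluid; cells with a missing fluid are excluded (counted in
    the report) and duplicate records raise.  Policy ``first`` resolves
    duplicates deterministically by taking the first record in stable sort
    order.  Returns (pairs table, report dict with exclusion counts).
    """
    if pairing_policy not in ("strict", "first"):
        raise ValueError(f"unknown pairing policy {pairing_policy!r}")
    recs = records.sort_values(["cell_id", "fluid_label"], kind="stable")
    report = {"n_cells": 0, "n_pairs": 0, "n_missing_fluid": 0, "n_duplicate": 0}
    rows = []
    for cell_id, grp in recs.groupby("cell_id", sort=True):
        report["n_cells"] += 1
        g1 = grp[grp["fluid_label"] == fluid1_label]
        g2 = grp[grp["fluid_label"] == fluid2_label]
        if len(g1) == 0 or len(g2) == 0:
            report["n_missing_fluid"] += 1
            continue
        if len(g1) > 1 or len(g2) > 1:
            report["n_duplicate"] += 1
            if pairing_policy == "strict":
                raise SchemaError(
                    f"cell {cell_id!r} has duplicate records "
                    f"({len(g1)} in {fluid1_label!r}, {len(g2)} in {fluid2_label!r}) "
                    "under strict pairing"
                )
        r1 = g1.iloc[0]
        r2 = g2.iloc[0]
        exposure = r2["exposure_time_s"]
        if pd.isna(exposure):
            exposure = r1["exposure_time_s"]
        rows.append(
            {
                "cell_id": cell_id,
                "mb1_fg": float(r1["buoyant_mass_fg"]),
                "mb2_fg": float(r2["buoyant_mass_fg"]),
                "exposure_time_s": float(exposure) if pd.notna(exposure) else np.nan,
            }
        )
        report["n_pairs"] += 1
    pairs = pd.DataFrame(rows, columns=["cell_id", "mb1_fg", "mb2_fg", "exposure_time_s"])
    return pairs, report


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a CLI run."""

    command: str
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    tool_version: str = ""
    schema_version: str = SCHEMA_VERSION
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, config: dict, seeds: dict) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config,
            seeds=seeds,
            tool_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
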