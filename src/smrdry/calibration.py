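"""Instrument calibration as simplified linear response models.

Buoyant mass is calibrated against polystyrene beads of known buoyant mass
(frequency peak height vs fg), and fluid density against NaCl standard
solutions (baseline resonance frequency vs g·cm⁻³).  Both are modelled as
straight lines; calibration is optional — pipelines may ingest buoyant
masses directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "MassCalibration",
    "DensityCalibration",
    "fit_mass_calibration",
    "apply_mass_calibration",
    "fit_density_calibration",
    "apply_density_calibration",
]


@dataclass(frozen=True)
class MassCalibration:
    """peak_height = sensitivity * buoyant_mass + offset."""

    sensitivity: float  # Hz per fg
    offset: float  # Hz
    residual_rms: float = 0.0  # Hz, fit quality for QC

    def __post_init__(self) -> None:
        if self.sensitivity == 0 or not math.isfinite(self.sensitivity):
            raise ValueError(f"sensitivity must be nonzero and finite, got {self.sensitivity!r}")


@dataclass(frozen=True)
class DensityCalibration:
    """baseline_freq = slope * density + intercept."""

    slope: float  # Hz per (g/cm^3)
    intercept: float  # Hz
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0 or not math.isfinite(self.slope):
            raise ValueError(f"slope must be nonzero and finite, got {self.slope!r}")


def _fit_line(x, y) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("calibration inputs must be equal-length 1-D sequences")
    if x.size < 2:
        raise DegenerateInputError(f"need >= 2 calibration points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("calibration points all share the same x value")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


def fit_mass_calibration(peak_heights, known_buoyant_masses) -> MassCalibration:
    """Least-squares line through (known buoyant mass, peak height) points."""
    slope, intercept, rms = _fit_line(known_buoyant_masses, peak_heights)
    return MassCalibration(sensitivity=slope, offset=intercept, residual_rms=rms)


def apply_mass_calibration(cal: MassCalibration, peak_height: float) -> float:
    """Invert the fitted line: buoyant mass (fg) for a peak height (Hz)."""
    peak = np.asarray(peak_height, dtype=float)
    if not np.all(np.isfinite(peak)):
        raise ValueError("peak_height must be finite")
    out = (peak - cal.offset) / cal.sensitivity
    return float(out) if out.ndim == 0 else out


def fit_density_calibration(baseline_freqs, known_densities) -> DensityCalibration:
    """Least-squares line through (known density, baseline frequency) points."""
    slope, intercept, rms = _fit_line(known_densities, baseline_freqs)
    return DensityCalibration(slope=slope, intercept=intercept, residual_rms=rms)


def apply_density_calibration(cal: DensityCalibration, baseline_freq: float) -> float:
    """Invert the fitted line: fluid density (g/cm^3) for a baseline frequency."""
    freq = np.asarray(baseline_freq, dtype=float)
    if not np.all(np.isfinite(freq)):
        raise ValueError("baseline_freq must be finite")
    out = (freq - cal.intercept) / cal.slope
    return float(out) if out.ndim == 0 else out
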