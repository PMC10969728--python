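"""Spray-dried powder arithmetic: yield, calibration, encapsulation efficiency.

Process yield is the percent of fed solids recovered as powder after cyclone
separation.  Encapsulation efficiency (EE) is the percent of the emulsion's
oil that survives drying inside the powder; oil content is quantified by UV
absorbance at 260 nm against a linear calibration curve (carvacrol standard,
Beer–Lambert regime).  Percent values above 100 are non-physical but can
arise from measurement artifacts — they are flagged with a warning, never
clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDesignError, NonPhysicalValueWarning


@dataclass(frozen=True)
class PowderBatch:
    """Masses for one spray-drying run (all grams)."""

    mass_powder_collected: float
    solid_fraction: float
    sample_total_weight: float
    oil_mass_in_powder: float | None = None
    oil_mass_in_emulsion: float | None = None

    def __post_init__(self):
        if self.mass_powder_collected < 0 or self.sample_total_weight < 0:
            raise ValueError("masses must be non-negative")
        if not (0 < self.solid_fraction <= 1):
            raise ValueError("solid_fraction must lie in (0, 1]")
        for m in (self.oil_mass_in_powder, self.oil_mass_in_emulsion):
            if m is not None and m < 0:
                raise ValueError("oil masses must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance–concentration calibration: A = slope·c + intercept."""

    slope: float
    intercept: float
    reference_standard: str = "carvacrol"

    def __post_init__(self):
        if self.slope <= 0:
            warnings.warn(
                "calibration slope is not positive; inversions will be suspect",
                NonPhysicalValueWarning,
                stacklevel=2,
            )


def process_yield(batch: PowderBatch) -> float:
    """Percent of fed solids recovered: 100 × collected / (solid_fraction × total)."""
    fed_solids = batch.solid_fraction * batch.sample_total_weight
    if fed_solids <= 0:
        raise ValueError("solid_fraction × sample_total_weight must be positive")
    y = 100.0 * batch.mass_powder_collected / fed_solids
    if y > 100.0:
        warnings.warn(
            f"process yield {y:.1f}% exceeds 100% (non-physical)",
            NonPhysicalValueWarning,
            stacklevel=2,
        )
    return y


def fit_calibration(
    concentrations: Sequence[float], absorbances: Sequence[float]
) -> CalibrationCurve:
    """OLS line absorbance = slope·concentration + intercept (g/L vs AU)."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size:
        raise ValueError("concentration and absorbance lengths differ")
    if c.size < 2 or np.unique(c).size < 2:
        raise DegenerateDesignError("need at least 2 distinct concentrations")
    slope, intercept = np.polyfit(c, a, 1)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept))


def absorbance_to_concentration(a: float, curve: CalibrationCurve) -> float:
    """Invert the calibration: c = (A − intercept) / slope, in g/L."""
    if curve.slope == 0:
        raise ValueError("zero calibration slope; inverse undefined")
    c = (a - curve.intercept) / curve.slope
    if c < 0:
        warnings.warn(
            f"negative concentration {c:.4g} g/L (absorbance below the intercept; "
            "extrapolation outside the calibrated range)",
            NonPhysicalValueWarning,
            stacklevel=2,
        )
    return c


def encapsulation_efficiency(oil_in_powder: float, oil_in_emulsion: float) -> float:
    """EE% = 100 × oil retained in powder / oil in the feed emulsion."""
    if oil_in_emulsion <= 0:
        raise ValueError("oil_in_emulsion must be positive")
    if oil_in_powder < 0:
        raise ValueError("oil_in_powder must be non-negative")
    ee = 100.0 * oil_in_powder / oil_in_emulsion
    if ee > 100.0:
        warnings.warn(
            f"encapsulation efficiency {ee:.1f}% exceeds 100% (non-physical)",
            NonPhysicalValueWarning,
            stacklevel=2,
        )
    return ee
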