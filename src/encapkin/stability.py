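"""Emulsion stability index and shelf-life kinetics.

The stability of a stored oil-in-water emulsion is tracked by turbidity:
absorbance at 600 nm of a diluted aliquot, measured daily.  The stability
index at day t is the percent ratio A_t/A_0 × 100 against the fresh
("activity") reading.  Because the reported fit intercepts track the
activity values, kinetic fits run on the *absolute* absorbance trajectory
reconstructed from (activity, percent-per-day) rather than on percents —
:func:`reconstruct_trajectory` inverts the index for that purpose.

Two decay laws are fit per sample × storage temperature: a zero-order line
(constant loss per day) and a first-order exponential (loss proportional to
the current level), both with rates in day⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import InsufficientDataError
from .models import FirstOrderKinetics, ZeroOrderKinetics
from .series import DecaySeries, SampleRecord


@dataclass(frozen=True)
class KineticFit:
    """Fitted order-0 or order-1 decay model.

    ``rate`` is stored as a non-negative magnitude with the sign carried by
    ``direction`` ("decay" or "growth"); ``signed_rate`` restores the signed
    slope/exponent as printed in regression tables.
    """

    order: int
    intercept: float
    rate: float
    direction: str
    se_intercept: float
    se_rate: float
    r_squared: float
    n_obs: int = 0

    def __post_init__(self):
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.rate < 0:
            raise ValueError("rate is a magnitude; use direction for the sign")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    @property
    def signed_rate(self) -> float:
        return -self.rate if self.direction == "decay" else self.rate

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.order == 0:
            return self.intercept + self.signed_rate * t
        return self.intercept * np.exp(self.signed_rate * t)


def compute_stability(a_t: float, a_0: float) -> float:
    """Stability index (percent) from absorbances: (a_t / a_0) × 100.

    Values above 100 are legal (day-to-day turbidity recoveries occur in
    practice) and are not capped.
    """
    if a_0 <= 0:
        raise ValueError("a_0 must be positive; the ratio is undefined")
    if a_t < 0:
        raise ValueError("a_t must be non-negative")
    return (a_t / a_0) * 100.0


def reconstruct_trajectory(
    activity_a0: float,
    stability_percents: Sequence[float],
    sample: SampleRecord | None = None,
) -> DecaySeries:
    """Absolute absorbance trajectory from an activity and daily percents.

    Day 0 is the activity itself (stability 100 %); day d is
    activity × S_d / 100.  This inverts :func:`compute_stability` exactly.
    """
    if activity_a0 <= 0:
        raise ValueError("activity must be positive")
    pct = np.asarray(stability_percents, dtype=float)
    if np.any(pct < 0):
        raise ValueError("stability percents must be non-negative")
    values = np.concatenate([[activity_a0], activity_a0 * pct / 100.0])
    times = np.arange(values.size, dtype=float)
    sid = sample.sample_id if sample is not None else ""
    return DecaySeries(times, values, sample_id=sid, condition=sample, time_unit="day")


def fit_zero_order(series: DecaySeries) -> KineticFit:
    """OLS line through the trajectory; rate in (value units)/day."""
    est = ZeroOrderKinetics().fit(series.times, series.values)
    return KineticFit(
        order=0,
        intercept=est.intercept_,
        rate=est.rate_,
        direction=est.direction_,
        se_intercept=est.se_intercept_,
        se_rate=est.se_slope_,
        r_squared=est.r_squared_,
        n_obs=est.n_obs_,
    )


def fit_first_order(series: DecaySeries, k_max: float = 10.0) -> KineticFit:
    """Nonlinear exponential fit on the original scale; rate in day⁻¹."""
    est = FirstOrderKinetics(k_max=k_max).fit(series.times, series.values)
    return KineticFit(
        order=1,
        intercept=est.amplitude_,
        rate=est.rate_,
        direction=est.direction_,
        se_intercept=est.se_amplitude_,
        se_rate=est.se_rate_,
        r_squared=est.r_squared_,
        n_obs=est.n_obs_,
    )


def average_r_squared(fits: Iterable[KineticFit]) -> float:
    """Arithmetic mean R² over a homogeneous collection of fits."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit collection")
    orders = {f.order for f in fits}
    if len(orders) > 1:
        raise ValueError(f"mixed fit orders {sorted(orders)}; average one order at a time")
    return float(np.mean([f.r_squared for f in fits]))


def detect_rate_peak(
    rates_by_temperature: Mapping[float, float], tol: float = 1e-9
) -> str:
    """Classify the rate-vs-temperature profile.

    "peaked" when the largest rate magnitude sits at a strictly interior
    temperature and strictly exceeds both neighbours — the signature of
    non-Arrhenius behaviour where degradation is fastest at an intermediate
    storage temperature.  "flat" when all rates agree within ``tol``;
    otherwise "monotone".
    """
    if len(rates_by_temperature) < 3:
        raise InsufficientDataError("need rates at >= 3 temperatures")
    temps = sorted(rates_by_temperature)
    rates = np.array([abs(rates_by_temperature[T]) for T in temps])
    if rates.max() - rates.min() <= tol:
        return "flat"
    i = int(np.argmax(rates))
    if 0 < i < len(rates) - 1 and rates[i] > rates[i - 1] and rates[i] > rates[i + 1]:
        return "peaked"
    return "monotone"
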