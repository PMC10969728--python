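"""Curve models as scikit-learn style estimators.

Three regressors cover the modeling chain:

``ZeroOrderKinetics``
    P(t) = P0 + s·t, ordinary least squares.  A constant-rate loss model: the
    property declines by the same amount per unit time regardless of its
    current level.

``FirstOrderKinetics``
    P(t) = P0·exp(s·t), nonlinear least squares on the original scale with a
    log-linear initializer.  Loss proportional to the current level.

``TruncatedFickianSlab``
    f(t) = A·exp(−D·π²·t/L²), the leading eigenfunction of one-dimensional
    Fickian diffusion out of a plane slab of characteristic length ``L``, fit
    for the effective diffusivity ``D`` over a long-time window where the
    single term is valid.

All estimators accept times as a 1-D array or an ``(n, 1)`` column and expose
fitted attributes with trailing underscores; they compose with sklearn
pipelines and ``get_params``/``set_params``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateDesignError,
    FitFailureError,
    InsufficientDataError,
)

#: τ = D·π²·t/L² at which the surface-form truncated model (4/π)·exp(−τ)
#: first drops to 1.0; earlier times are non-physical under the one-term model.
TAU_PHYSICAL_MIN = math.log(4.0 / math.pi)

#: Prefactor of the one-term model by convention: "surface" is the
#: surface-concentration form (4/π), "series" the leading mass-average
#: eigenfunction coefficient (8/π²).
AMPLITUDES = {"surface": 4.0 / math.pi, "series": 8.0 / math.pi**2}


def _as_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("X must be a 1-D array of times or an (n, 1) column")
    return t


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 − SS_res/SS_tot about the mean; 1.0 for a perfect fit to constant data."""
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-300 else 0.0
    return 1.0 - ss_res / ss_tot


class ZeroOrderKinetics(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line P(t) = P0 + s·t.

    Fitted attributes
    -----------------
    intercept_ : fitted level at t = 0 (P0)
    slope_ : signed rate (per time unit of the input)
    rate_ : |slope_|; direction_ is "decay" or "growth"
    se_intercept_, se_slope_ : standard errors (0 when there are no residual
        degrees of freedom, i.e. a saturated two-point fit)
    r_squared_ : coefficient of determination about the mean
    """

    def fit(self, X, y):
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("X and y lengths differ")
        if t.size < 2:
            raise InsufficientDataError("need at least 2 points for a line")
        if np.unique(t).size < 2:
            raise DegenerateDesignError("all times identical; slope is undefined")

        A = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        dof = t.size - 2
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(A.T @ A)
        self.intercept_ = float(beta[0])
        self.slope_ = float(beta[1])
        self.rate_ = abs(self.slope_)
        self.direction_ = "decay" if self.slope_ < 0 else "growth"
        self.se_intercept_ = float(np.sqrt(cov[0, 0]))
        self.se_slope_ = float(np.sqrt(cov[1, 1]))
        self.r_squared_ = _r_squared(y, A @ beta)
        self.n_obs_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times(X)
        return self.intercept_ + self.slope_ * t


class FirstOrderKinetics(RegressorMixin, BaseEstimator):
    """Exponential model P(t) = P0·exp(s·t) fit by nonlinear least squares.

    The fit runs on the untransformed values (so the loss matches the
    measurement scale), initialized from the log-linear regression of
    ln P on t.  The signed exponent s is bounded to ``[-k_max, k_max]``.

    Parameters
    ----------
    k_max : bound on |s| per time unit of the input (default 10, generous for
        per-day stability rates; release rates in s⁻¹ are far inside it).
    maxfev : iteration budget for the optimizer; exceeding it raises
        :class:`FitFailureError` carrying the log-linear initializer's result.
    """

    def __init__(self, k_max: float = 10.0, maxfev: int = 10000):
        self.k_max = k_max
        self.maxfev = maxfev

    @staticmethod
    def _model(t, p0, s):
        return p0 * np.exp(s * t)

    def fit(self, X, y):
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("X and y lengths differ")
        if t.size < 3:
            raise InsufficientDataError("need at least 3 points for the exponential fit")
        if np.any(y <= 0):
            raise ValueError("all values must be positive to initialize the exponential fit")

        s0, logp0 = np.polyfit(t, np.log(y), 1)
        p0_init = float(np.exp(logp0))
        s_init = float(np.clip(s0, -self.k_max, self.k_max))
        try:
            popt, pcov = curve_fit(
                self._model,
                t,
                y,
                p0=[p0_init, s_init],
                bounds=([0.0, -self.k_max], [np.inf, self.k_max]),
                maxfev=self.maxfev,
            )
        except RuntimeError as exc:
            raise FitFailureError(
                f"exponential fit did not converge: {exc}",
                initial_result={"amplitude": p0_init, "rate": abs(s_init),
                                "direction": "decay" if s_init < 0 else "growth"},
            ) from exc

        perr = np.sqrt(np.diag(pcov))
        self.amplitude_ = float(popt[0])
        self.exponent_ = float(popt[1])
        self.rate_ = abs(self.exponent_)
        self.direction_ = "decay" if self.exponent_ < 0 else "growth"
        self.se_amplitude_ = float(perr[0])
        self.se_rate_ = float(perr[1])
        self.r_squared_ = _r_squared(y, self._model(t, *popt))
        self.n_obs_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times(X)
        return self._model(t, self.amplitude_, self.exponent_)


class TruncatedFickianSlab(RegressorMixin, BaseEstimator):
    """One-term Fickian slab model f(t) = A·exp(−D·π²·t/L²), fit for D.

    The single eigenfunction is only valid at long times; the fit therefore
    restricts itself to points with dimensionless time τ = D·π²·t/L² at or
    above ``tau_min``, re-evaluating the window from the current D estimate
    until the window stabilises.  ``tau_min = ln(4/π)`` by default — the time
    at which the surface-form model first drops to 1 — and may be set to 0 to
    mimic naive whole-curve fitting.

    Parameters
    ----------
    L : characteristic length of the slab in metres.  Required; there is no
        default because the geometric convention (half-thickness vs another
        length) materially changes D and must be the caller's explicit choice.
    amplitude : "surface" (4/π) or "series" (8/π²), or a positive float.
    tau_min : lower edge of the dimensionless-time fit window.
    max_iter : window re-evaluation budget.

    Fitted attributes: ``diffusivity_`` (m²/s), ``se_diffusivity_``,
    ``r_squared_`` (within the window), ``window_mask_``, ``n_iter_``.
    """

    def __init__(self, L: float | None = None, amplitude: str | float = "surface",
                 tau_min: float = TAU_PHYSICAL_MIN, max_iter: int = 50):
        self.L = L
        self.amplitude = amplitude
        self.tau_min = tau_min
        self.max_iter = max_iter

    def _amplitude_value(self) -> float:
        if isinstance(self.amplitude, str):
            try:
                return AMPLITUDES[self.amplitude]
            except KeyError:
                raise ValueError(
                    f"unknown amplitude convention {self.amplitude!r}; "
                    f"use one of {sorted(AMPLITUDES)} or a positive float"
                ) from None
        a = float(self.amplitude)
        if a <= 0:
            raise ValueError("amplitude must be positive")
        return a

    def fit(self, X, y):
        if self.L is None or self.L <= 0:
            raise ValueError("L must be a positive length in metres (no default)")
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("X and y lengths differ")
        A = self._amplitude_value()
        rate = math.pi**2 / self.L**2  # exponent per unit D·t

        def model(t, D):
            return A * np.exp(-D * rate * t)

        # log-linear initializer on the positive part of the curve
        pos = y > 0
        if pos.sum() >= 2 and np.unique(t[pos]).size >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos] / A), 1)[0]
            d_hat = max(-slope / rate, 1e-18)
        else:
            d_hat = 1e-10  # scale of typical liquid-in-solid diffusivities

        prev_mask = None
        for n_iter in range(1, self.max_iter + 1):
            mask = d_hat * rate * t >= self.tau_min
            if mask.sum() < 3:
                raise InsufficientDataError(
                    f"only {int(mask.sum())} points at tau >= {self.tau_min:.4g}; "
                    "need at least 3"
                )
            if prev_mask is not None and np.array_equal(mask, prev_mask):
                break
            prev_mask = mask
            try:
                popt, pcov = curve_fit(
                    model, t[mask], y[mask], p0=[d_hat], bounds=(0.0, np.inf)
                )
            except RuntimeError as exc:
                raise FitFailureError(
                    f"Fickian fit did not converge: {exc}",
                    initial_result={"diffusivity": d_hat},
                ) from exc
            d_hat = float(popt[0])
        else:
            raise FitFailureError(
                f"fit window did not stabilise in {self.max_iter} iterations",
                initial_result={"diffusivity": d_hat},
            )

        self.diffusivity_ = d_hat
        self.se_diffusivity_ = float(np.sqrt(pcov[0, 0]))
        self.r_squared_ = _r_squared(y[mask], model(t[mask], d_hat))
        self.window_mask_ = mask
        self.n_iter_ = n_iter
        self.amplitude_value_ = A
        return self

    def predict(self, X):
        t = _as_times(X)
        return self.amplitude_value_ * np.exp(
            -self.diffusivity_ * math.pi**2 * t / self.L**2
        )
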