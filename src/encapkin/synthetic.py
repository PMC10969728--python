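"""Synthetic measurement generator with known ground truth.

Stands in for the two raw data streams of an encapsulation study:

* **Stability trajectories** — absorbance of a stored emulsion sampled daily
  at a handful of time points (3–4 in the emulated design), decaying by a
  zero-order line or first-order exponential.
* **Release curves** — remaining oil fraction of a disc monolith sampled
  every 30 min, following the full Fickian slab eigenfunction series (or its
  one-term truncation), optionally converted to gravimetric weights
  ``plateau_mass + M0 · remaining(t)`` to emulate weighing the whole monolith
  including its non-volatile carrier.

Noise is additive Gaussian on the measured signal — matching the symmetric
± uncertainties instruments of this kind report — and is never clipped, so
negative absorbances can occur just as they can from real spectrophotometer
arithmetic.  Every config carries a mandatory seed; there is no hidden
global random state, and equal configs produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidConfigError
from .release import series_remaining_fraction, slab_remaining_fraction
from .series import DecaySeries

MODELS = ("zero_order", "first_order", "fickian_full", "fickian_truncated")

#: Default stability measurement noise, absorbance units.  Chosen from the
#: dispersion of replicate emulsion-turbidity readings in studies of this
#: design, where absolute absorbance standard deviations cluster around
#: 3–5 AU on signals of 100–300 AU.
STABILITY_NOISE_SD = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth + sampling plan for one simulated trajectory.

    Truth parameters (use the ones the chosen model needs):

    p0 : initial property level (absorbance AU) for the decay models
    k : rate constant (per day for stability models)
    d : diffusivity, m²/s; L : slab characteristic length, m
    m0 : volatile oil mass, g (gravimetric conversion of release curves)
    plateau_mass : non-volatile carrier mass, g

    ``dt`` is in days for the stability models and seconds for the release
    models.  ``noise_sd`` shares units with the simulated signal.
    """

    seed: int
    model: str
    n_points: int
    dt: float
    noise_sd: float = 0.0
    p0: float | None = None
    k: float | None = None
    d: float | None = None
    L: float | None = None
    m0: float = 1.0
    n_terms: int = 50
    plateau_mass: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise InvalidConfigError(f"model must be one of {MODELS}")
        if self.n_points <= 0 or self.dt <= 0:
            raise InvalidConfigError("n_points and dt must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.n_terms < 1:
            raise InvalidConfigError("n_terms must be >= 1")
        if self.plateau_mass < 0:
            raise InvalidConfigError("plateau_mass must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points, dtype=float) * self.dt

    def truth(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("seed",) and getattr(self, f.name) is not None
        }


def _add_noise(values: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    if config.noise_sd == 0:
        return values
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return values + rng.normal(0.0, config.noise_sd, size=values.shape)


def gen_stability_trajectory(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> DecaySeries:
    """One simulated absorbance-vs-day trajectory.

    zero_order: value(t) = p0 − k·t; first_order: value(t) = p0·exp(−k·t);
    plus Normal(0, noise_sd) on each point.  Values are not clipped.
    """
    if config.model not in ("zero_order", "first_order"):
        raise InvalidConfigError("model must be zero_order or first_order")
    if config.p0 is None or config.p0 <= 0:
        raise InvalidConfigError("truth p0 must be positive")
    if config.k is None or config.k < 0:
        raise InvalidConfigError("truth k must be non-negative")
    t = config.times
    if config.model == "zero_order":
        values = config.p0 - config.k * t
    else:
        values = config.p0 * np.exp(-config.k * t)
    return DecaySeries(t, _add_noise(values, config, rng), time_unit="day")


def gen_release_curve(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    as_weights: bool = False,
) -> DecaySeries:
    """One simulated slab-release curve sampled at t = 0, dt, 2·dt, … seconds.

    ``fickian_full`` evaluates the untruncated slab solution (eigenfunction
    series at long times, exact short-time form near t = 0, so the noiseless
    curve starts at exactly 1); ``fickian_truncated`` keeps only the leading
    eigenfunction term (the 8/π² mass-average coefficient).  With ``as_weights`` the fraction is converted
    to grams as ``plateau_mass + m0 · remaining(t)`` before noise is added.
    """
    if config.model not in ("fickian_full", "fickian_truncated"):
        raise InvalidConfigError("model must be fickian_full or fickian_truncated")
    if config.d is None or config.d <= 0:
        raise InvalidConfigError("truth d must be positive")
    if config.L is None or config.L <= 0:
        raise InvalidConfigError("truth L must be positive")
    t = config.times
    if config.model == "fickian_full":
        remaining = slab_remaining_fraction(config.d, config.L, t, n_terms=config.n_terms)
    else:
        remaining = series_remaining_fraction(config.d, config.L, t, n_terms=1)
    values = config.plateau_mass + config.m0 * remaining if as_weights else remaining
    return DecaySeries(t, _add_noise(values, config, rng), time_unit="s")


def gen_ensemble(
    config: SimulationConfig, n_replicates: int, as_weights: bool = False
) -> list[DecaySeries]:
    """Independent replicate trajectories from one config.

    Replicates draw from child streams spawned off ``config.seed``, so the
    ensemble is reproducible as a whole and each replicate is independent.
    """
    if n_replicates < 1:
        raise InvalidConfigError("n_replicates must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(n_replicates)
    gen = (
        gen_stability_trajectory
        if config.model in ("zero_order", "first_order")
        else lambda c, r: gen_release_curve(c, r, as_weights=as_weights)
    )
    return [gen(config, np.random.default_rng(s)) for s in streams]


def write_series_csv(
    series: Iterable[DecaySeries],
    path: str | Path,
    configs: Sequence[SimulationConfig] | SimulationConfig | None = None,
    condition: str = "",
) -> Path:
    """Write tidy CSV (sample_id, condition, time, value) plus a JSON sidecar.

    The sidecar (``<path>.truth.json``) records seeds and ground-truth
    parameters so parameter-recovery checks can close the loop.
    """
    import pandas as pd

    path = Path(path)
    frames = []
    for i, s in enumerate(series):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id or f"sim{i}",
                    "condition": condition,
                    "time": s.times,
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    if configs is not None:
        if isinstance(configs, SimulationConfig):
            configs = [configs]
        sidecar = [
            {"seed": c.seed, "model": c.model, "truth": c.truth()} for c in configs
        ]
        Path(f"{path}.truth.json").write_text(json.dumps(sidecar, indent=2))
    return path
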