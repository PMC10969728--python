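"""Lightweight containers for time-resolved measurements.

A :class:`DecaySeries` holds one measured trajectory — absorbance of a stored
emulsion versus day, or monolith weight / remaining oil fraction versus
second — together with the identity of the sample it belongs to.  Times are
kept in the natural unit of the experiment (days for emulsion stability,
seconds for release); unit conversion is the caller's job and the ``time_unit``
tag exists so mistakes are visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleRecord:
    """Formulation identity of one emulsion sample.

    Gum concentrations are in g per 100 g of emulsion.  The study design keeps
    guar + xanthan at 1 g/100 g total; other totals are legal for new data and
    only provoke a warning.
    """

    sample_id: str
    guar_conc: float = 0.0
    xanthan_conc: float = 0.0
    temperature: float | None = None

    def __post_init__(self):
        if self.guar_conc < 0 or self.xanthan_conc < 0:
            raise ValueError("gum concentrations must be non-negative")
        total = self.guar_conc + self.xanthan_conc
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"sample {self.sample_id}: guar + xanthan = {total:g} g/100 g "
                "(study design uses 1.0)",
                stacklevel=2,
            )
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive (degrees Celsius)")


@dataclass(frozen=True)
class DecaySeries:
    """One time-stamped trajectory of a decaying property."""

    times: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    condition: SampleRecord | None = None
    time_unit: str = "day"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValueError("times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def replace_values(self, values) -> "DecaySeries":
        return DecaySeries(self.times, values, self.sample_id, self.condition, self.time_unit)

    def head(self, n: int) -> "DecaySeries":
        return DecaySeries(
            self.times[:n], self.values[:n], self.sample_id, self.condition, self.time_unit
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "time": self.times, "value": self.values}
        )
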