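"""Sample-level parameter table and Pearson correlation matrix.

The endpoint of the pipeline: one row per formulation with its emulsion
activity, stability rate constants, the two effective-diffusivity routes and
the encapsulation efficiency, and the pairwise Pearson correlations between
those columns.  Temperature-resolved quantities (activity, stability rates)
must be collapsed to one value per sample first; the aggregation mode is an
explicit, recorded choice because different modes give materially different
activity correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import JoinError

PARAMETER_COLUMNS = (
    "emulsion_activity",
    "zero_order_rate",
    "first_order_rate",
    "d_from_k",
    "d_eff_fick",
    "encapsulation_efficiency",
)

AGGREGATIONS = ("mean", "T5", "T20", "T35")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Square Pearson matrix with its column labels and sample count."""

    labels: tuple[str, ...]
    r: np.ndarray
    n: int

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.labels), len(self.labels)):
            raise ValueError("r must be square and match labels")
        if not np.allclose(r, r.T):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("|r| cannot exceed 1")
        object.__setattr__(self, "r", r)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))

    def to_long(self) -> pd.DataFrame:
        rows = [
            (a, b, float(self.r[i, j]))
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
        ]
        return pd.DataFrame(rows, columns=["var1", "var2", "r"])


def _aggregate(df: pd.DataFrame, value_cols: list[str], aggregation: str) -> pd.DataFrame:
    """Collapse temperature-resolved rows to one per sample."""
    if aggregation == "mean":
        return df.groupby("sample_id", sort=True)[value_cols].mean()
    temp = float(aggregation[1:])
    sub = df[df["temperature_C"] == temp]
    if sub.empty:
        raise ValueError(f"no rows at temperature {temp} for aggregation {aggregation!r}")
    return sub.set_index("sample_id")[value_cols].sort_index()


def build_parameter_table(
    activity: pd.DataFrame,
    stability_rates: pd.DataFrame,
    diffusivities: pd.DataFrame,
    powder_metrics: pd.DataFrame,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Join per-sample parameters into one table (rows = samples).

    Parameters
    ----------
    activity : columns ``sample_id, temperature_C, emulsion_activity`` (AU).
    stability_rates : columns ``sample_id, temperature_C, zero_order_rate,
        first_order_rate`` (day⁻¹ magnitudes).
    diffusivities : columns ``sample_id, d_from_k, d_eff_fick`` (m²/s, any
        consistent scale).
    powder_metrics : columns ``sample_id, encapsulation_efficiency`` (%).
    aggregation : how temperature-resolved quantities collapse to one value
        per sample: "mean" over the measured temperatures, or "T5"/"T20"/"T35"
        to select a single storage temperature.

    The mode is stamped into ``result.attrs["aggregation"]``.  Samples present
    in one input but missing from another raise :class:`JoinError` listing the
    absentees.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")

    act = _aggregate(activity, ["emulsion_activity"], aggregation)
    rates = _aggregate(
        stability_rates, ["zero_order_rate", "first_order_rate"], aggregation
    )
    diff = diffusivities.set_index("sample_id")[["d_from_k", "d_eff_fick"]].sort_index()
    powder = powder_metrics.set_index("sample_id")[["encapsulation_efficiency"]].sort_index()

    pieces = {"activity": act, "stability_rates": rates,
              "diffusivities": diff, "powder_metrics": powder}
    all_ids = sorted(set().union(*(set(p.index) for p in pieces.values())))
    missing = {
        name: sorted(set(all_ids) - set(p.index)) for name, p in pieces.items()
    }
    absent = {name: ids for name, ids in missing.items() if ids}
    if absent:
        raise JoinError(
            f"samples missing from inputs: {absent}",
            missing=sorted({i for ids in absent.values() for i in ids}),
        )

    table = pd.concat([act, rates, diff, powder], axis=1).loc[all_ids]
    table = table[list(PARAMETER_COLUMNS)]
    table.attrs["aggregation"] = aggregation
    return table


def correlation_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """All pairwise Pearson correlations of a complete parameter table."""
    if table.isna().any().any():
        raise ValueError("parameter table has missing cells")
    if len(table) < 3:
        raise ValueError("need at least 3 samples for correlations")
    labels = tuple(table.columns)
    p = len(labels)
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r[i, j] = r[j, i] = pearson_r(table.iloc[:, i], table.iloc[:, j])
    return CorrelationMatrix(labels=labels, r=r, n=len(table))
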