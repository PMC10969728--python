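"""File formats, run configuration, and the end-to-end pipeline driver.

Input CSVs are comma-separated UTF-8 with a header and "." decimals, in the
experiment's natural time units:

* stability schema: ``sample_id, temperature_C, day, absorbance``
* release schema:   ``sample_id, time_min, weight_g``

Internally release times are seconds.  The pipeline writes a stability-fits
table, a release/diffusivity table with a geometry-provenance column, the
parameter table, the correlation matrix (square and long form), and a JSON
run log recording versions, seed, aggregation mode and the characteristic
lengths used — enough to reproduce any run from its config alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlate, release, stability
from .exceptions import SchemaError
from .series import DecaySeries

SCHEMAS = {
    "stability": ("sample_id", "temperature_C", "day", "absorbance"),
    "release": ("sample_id", "time_min", "weight_g"),
}


def read_timeseries(path: str | Path, schema: str) -> dict:
    """Read a tidy CSV into a dict of :class:`DecaySeries`.

    Stability files are keyed by ``(sample_id, temperature_C)`` with times in
    days; release files by ``sample_id`` with times converted to seconds.
    Rows with unparseable numbers are dropped with a warning that lists their
    line numbers; a missing column raises :class:`SchemaError`.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    numeric = [c for c in cols if c != "sample_id"]
    parsed = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna().any(axis=1) | df["sample_id"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(f"{path}: dropped {bad.sum()} malformed row(s) at lines {lines}")
        df = df[~bad]
        parsed = parsed[~bad]
    df = df.assign(**{c: parsed[c] for c in numeric})

    if df.empty:
        warnings.warn(f"{path}: no data rows")
        return {}

    out = {}
    if schema == "stability":
        for (sid, temp), grp in df.groupby(["sample_id", "temperature_C"], sort=True):
            grp = grp.sort_values("day")
            out[(sid, float(temp))] = DecaySeries(
                grp["day"].to_numpy(float), grp["absorbance"].to_numpy(float),
                sample_id=sid, time_unit="day",
            )
    else:
        for sid, grp in df.groupby("sample_id", sort=True):
            grp = grp.sort_values("time_min")
            out[sid] = DecaySeries(
                grp["time_min"].to_numpy(float) * 60.0,
                grp["weight_g"].to_numpy(float),
                sample_id=sid, time_unit="s",
            )
    return out


def write_timeseries(collection: dict, path: str | Path, schema: str) -> Path:
    """Inverse of :func:`read_timeseries` (release times written in minutes)."""
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
    rows = []
    if schema == "stability":
        for (sid, temp), s in collection.items():
            for t, v in zip(s.times, s.values):
                rows.append((sid, temp, t, v))
    else:
        for sid, s in collection.items():
            for t, v in zip(s.times, s.values):
                rows.append((sid, t / 60.0, v))
    pd.DataFrame(rows, columns=list(SCHEMAS[schema])).to_csv(path, index=False)
    return Path(path)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, explicit and serialisable.

    Exactly one of ``release_weights_csv`` (raw monolith weights; the fully
    computed path) or ``release_fits_csv`` (pre-fitted per-minute rate
    constants and Fickian diffusivities, columns ``sample_id, k_per_min,
    d_eff_1e10``; used when raw curves are unavailable) must be given.
    Both characteristic lengths are mandatory — there is no default L.
    """

    stability_csv: str
    powder_csv: str
    L_kinetic: float | None = None
    L_fick: float | None = None
    release_weights_csv: str | None = None
    release_fits_csv: str | None = None
    aggregation: str = "mean"
    plateau_tolerance: float = 1e-4
    plateau_mass: float = 0.0
    seed: int = 0
    out_dir: str = "encapkin_out"

    def validate(self) -> None:
        if self.L_kinetic is None or self.L_fick is None:
            raise ValueError("L_kinetic and L_fick are required; no default geometry")
        if self.L_kinetic <= 0 or self.L_fick <= 0:
            raise ValueError("characteristic lengths must be positive")
        if (self.release_weights_csv is None) == (self.release_fits_csv is None):
            raise ValueError(
                "provide exactly one of release_weights_csv or release_fits_csv"
            )
        if self.aggregation not in correlate.AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {correlate.AGGREGATIONS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str, sample, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed for sample {sample!r}: {exc}") from exc


def fit_stability_tables(series_by_key: dict) -> pd.DataFrame:
    """Zero- and first-order fits for every (sample, temperature) trajectory."""
    rows = []
    for (sid, temp), s in sorted(series_by_key.items()):
        z = _stage("fit_zero_order", sid, stability.fit_zero_order, s)
        f = _stage("fit_first_order", sid, stability.fit_first_order, s)
        rows.append(
            {
                "sample_id": sid, "temperature_C": temp,
                "zero_intercept": z.intercept, "zero_slope": z.signed_rate,
                "zero_se_intercept": z.se_intercept, "zero_se_slope": z.se_rate,
                "zero_r2": z.r_squared,
                "first_intercept": f.intercept, "first_slope": f.signed_rate,
                "first_se_intercept": f.se_intercept, "first_se_slope": f.se_rate,
                "first_r2": f.r_squared,
            }
        )
    return pd.DataFrame(rows)


def fit_release_tables(weights_by_sample: dict, config: RunConfig) -> pd.DataFrame:
    """Trim, normalize and fit every release curve by both diffusivity routes."""
    rows = []
    for sid, s in sorted(weights_by_sample.items()):
        trimmed = _stage("trim_at_plateau", sid, release.trim_at_plateau,
                         s, config.plateau_tolerance)
        frac = _stage("normalize_release", sid, release.normalize_release,
                      trimmed, config.plateau_mass)
        rfit, dest = _stage("estimate_diffusivities", sid, release.estimate_diffusivities,
                            frac, config.L_kinetic, config.L_fick)
        rows.append(
            {
                "sample_id": sid, "m0": rfit.m0, "k_per_min": rfit.k_per_min,
                "r2_first": rfit.r_squared,
                "d_from_k": dest.d_from_k, "L_kinetic": dest.L_from_k,
                "d_eff_fick": dest.d_eff_fick, "L_fick": dest.L_fick,
                "r2_fick": dest.r_squared_fick,
            }
        )
    return pd.DataFrame(rows)


def release_table_from_fits(fits_csv: str | Path, config: RunConfig) -> pd.DataFrame:
    """Diffusivity table from pre-fitted release constants.

    The kinetic-route diffusivity is computed here from the per-minute rate
    constant and ``L_kinetic``; the Fickian diffusivity is taken as given
    (column ``d_eff_1e10``, in 10⁻¹⁰ m²/s as release tables print it).
    """
    df = pd.read_csv(fits_csv, dtype={"sample_id": str})
    need = {"sample_id", "k_per_min", "d_eff_1e10"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{fits_csv}: need columns {sorted(need)}")
    df = df.sort_values("sample_id")
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "k_per_min": df["k_per_min"],
            "d_from_k": [
                release.k_to_diffusivity(k / 60.0, config.L_kinetic)
                for k in df["k_per_min"]
            ],
            "L_kinetic": config.L_kinetic,
            "d_eff_fick": df["d_eff_1e10"] * 1e-10,
            "L_fick": config.L_fick,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole chain and write all outputs under ``config.out_dir``.

    Returns a dict with the output paths, the parameter table and the
    correlation matrix.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stab_series = read_timeseries(config.stability_csv, "stability")
    fits = fit_stability_tables(stab_series)

    if config.release_weights_csv is not None:
        rel = fit_release_tables(
            read_timeseries(config.release_weights_csv, "release"), config
        )
    else:
        rel = release_table_from_fits(config.release_fits_csv, config)

    powder = pd.read_csv(config.powder_csv, dtype={"sample_id": str})
    if "encapsulation_efficiency" not in powder.columns:
        raise SchemaError(f"{config.powder_csv}: need column encapsulation_efficiency")

    activity = pd.DataFrame(
        {
            "sample_id": [k[0] for k in stab_series],
            "temperature_C": [k[1] for k in stab_series],
            "emulsion_activity": [s.values[0] for s in stab_series.values()],
        }
    )
    rates = fits.assign(
        zero_order_rate=fits["zero_slope"].abs(),
        first_order_rate=fits["first_slope"].abs(),
    )[["sample_id", "temperature_C", "zero_order_rate", "first_order_rate"]]

    table = correlate.build_parameter_table(
        activity, rates, rel, powder, aggregation=config.aggregation
    )
    matrix = correlate.correlation_matrix(table)

    paths = {
        "stability_fits": out / "stability_fits.csv",
        "release": out / "release_diffusivity.csv",
        "parameter_table": out / "parameter_table.csv",
        "correlation_matrix": out / "correlation_matrix.csv",
        "correlation_long": out / "correlation_long.csv",
        "run_log": out / "run_log.json",
    }
    fits.to_csv(paths["stability_fits"], index=False)
    rel.to_csv(paths["release"], index=False)
    table.to_csv(paths["parameter_table"])
    matrix.to_frame().to_csv(paths["correlation_matrix"])
    matrix.to_long().to_csv(paths["correlation_long"], index=False)

    log = {
        "config": asdict(config),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "encapkin": _package_version(),
        },
        "aggregation": config.aggregation,
        "geometry": {"L_kinetic": config.L_kinetic, "L_fick": config.L_fick},
        "seed": config.seed,
        "n_stability_series": len(stab_series),
        "n_samples": int(len(table)),
    }
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))

    return {"paths": paths, "parameter_table": table, "correlation": matrix}


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("encapkin")
    except PackageNotFoundError:
        return "unknown"
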