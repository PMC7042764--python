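"""Annual climate covariates of vital rates, built from point samples.

Three covariates enter the vital-rate models, one value per stratum and
year:

* ``cmd`` — winter (Dec-Feb) climate-moisture-deficit anomaly on the
  wintering range (mm).  CMD is the monthly excess of atmospheric
  evaporative demand over precipitation, summed over the season; the
  anomaly is the departure from a fixed 1961-1990 normal.
* ``temp`` — spring (Feb-May) mean-temperature anomaly on the breeding
  range (degrees C relative to the same normal period).
* ``tw`` — mean tailwind component (m/s) over the stratum's spring
  migration window, averaged across reanalysis grid points, two pressure
  levels and all 6-hourly samples except midday (when songbirds do not
  migrate).

The winter labelled year t spans Dec of t-1 through Feb of t and predicts
survival over the interval ending at breeding season t.

This module consumes already-extracted point/grid values; interpolation of
gridded climate and reanalysis retrieval are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSeries",
    "compute_cmd",
    "seasonal_anomaly",
    "tailwind_component",
    "migration_tailwind",
    "winter_cmd_anomaly",
    "spring_temperature_anomaly",
    "standardize_covariates",
]

COVARIATE_NAMES = ("cmd", "tw", "temp")


@dataclass
class CovariateSeries:
    """Per-stratum annual climate covariates with a standardization record.

    ``frame`` has one row per (stratum, year) with columns ``cmd``, ``tw``,
    ``temp`` on the anomaly scale.  After :func:`standardize_covariates`,
    z-scored columns ``cmd_z``/``tw_z``/``temp_z`` are added and
    ``standardization`` records the (mean, sd) used per stratum and
    covariate so coefficients can be reported per anomaly unit.
    """

    frame: pd.DataFrame
    standardization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {"stratum", "year", *COVARIATE_NAMES}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"covariate frame missing columns {sorted(missing)}")
        if self.frame.duplicated(subset=["stratum", "year"]).any():
            raise ValueError("covariate frame has duplicated (stratum, year) rows")
        self.frame = self.frame.sort_values(["stratum", "year"]).reset_index(drop=True)

    def values(self, name: str, strata, years) -> np.ndarray:
        """Dense (n_strata, n_years) array of one covariate, aligned to labels."""
        pivot = self.frame.pivot(index="stratum", columns="year", values=name)
        try:
            arr = pivot.loc[list(strata), list(years)].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"covariate {name!r} missing entries: {exc}") from exc
        if np.isnan(arr).any():
            raise ValueError(f"covariate {name!r} has missing (stratum, year) cells")
        return arr

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def compute_cmd(
    monthly_eref: np.ndarray, monthly_precip: np.ndarray, *, clamp: bool = True
) -> float:
    """Seasonal climate moisture deficit (mm) from monthly demand and precipitation.

    With ``clamp`` (the conventional definition) each month contributes
    ``max(0, Eref - precip)``: a wet month cannot offset a dry one.  The
    unclamped sum of signed differences is selectable for comparison.
    """
    eref = np.asarray(monthly_eref, dtype=float)
    precip = np.asarray(monthly_precip, dtype=float)
    if eref.shape != precip.shape:
        raise ValueError(
            f"monthly series length mismatch: {eref.shape} vs {precip.shape}"
        )
    if (precip < 0).any():
        raise ValueError("negative monthly precipitation")
    diff = eref - precip
    if clamp:
        diff = np.maximum(diff, 0.0)
    return float(diff.sum())


def seasonal_anomaly(annual: pd.DataFrame, normal: pd.Series) -> pd.Series:
    """Mean departure of annual point values from fixed per-point normals.

    ``annual`` is a point x year table (index = point ids); ``normal`` maps
    the same point ids to their 1961-1990 normal.  The anomaly for year t is
    the mean over points of (value - normal), which for a fixed point set
    equals mean(annual) - mean(normal).
    """
    missing = set(annual.index) - set(normal.index)
    if missing:
        raise ValueError(f"points without a normal value: {sorted(missing)[:5]}")
    dev = annual.sub(normal.loc[annual.index], axis=0)
    return dev.mean(axis=0)


def tailwind_component(u, v, bearing_deg):
    """Projection of the wind vector onto a migration bearing (m/s).

    ``bearing_deg`` is degrees clockwise from north; u is the eastward and
    v the northward wind component.  Positive values push a bird along the
    bearing.
    """
    theta = np.deg2rad(bearing_deg)
    return u * np.sin(theta) + v * np.cos(theta)


def _window_mask(ts: pd.Series, start: tuple[int, int], end: tuple[int, int]) -> pd.Series:
    """True where timestamps fall in the (month, day) window, inclusive."""
    key = ts.dt.month * 100 + ts.dt.day
    lo = start[0] * 100 + start[1]
    hi = end[0] * 100 + end[1]
    if lo <= hi:
        return (key >= lo) & (key <= hi)
    return (key >= lo) | (key <= hi)  # window wrapping the year end


def migration_tailwind(
    winds: pd.DataFrame,
    window: tuple[tuple[int, int], tuple[int, int]],
    bearing_deg: float,
) -> pd.Series:
    """Per-year mean tailwind over a migration window.

    ``winds`` has columns ``point, datetime, level_mb, u, v`` (datetime
    parseable by pandas).  The mean is a flat average over every grid
    point, both pressure levels and all 6-hourly timestamps in the window,
    excluding hour 12 (midday, when migrants are sedentary).
    """
    needed = {"point", "datetime", "level_mb", "u", "v"}
    missing = needed - set(winds.columns)
    if missing:
        raise ValueError(f"wind table missing columns {sorted(missing)}")
    ts = pd.to_datetime(winds["datetime"])
    keep = _window_mask(ts, *window) & (ts.dt.hour != 12)
    sub = winds.loc[keep]
    if sub.empty:
        raise ValueError("no wind samples inside the migration window")
    tw = tailwind_component(sub["u"].to_numpy(), sub["v"].to_numpy(), bearing_deg)
    out = pd.Series(tw, index=ts.loc[keep].dt.year.to_numpy()).groupby(level=0).mean()
    out.index.name = "year"
    return out


def winter_cmd_anomaly(
    climate: pd.DataFrame,
    normals: pd.DataFrame,
    years,
) -> pd.Series:
    """Per-year winter CMD anomaly from monthly point climate samples.

    ``climate`` has columns ``point, year, month, eref, precip`` with
    calendar-labelled months; Dec of year t-1 is pooled with Jan-Feb of
    year t into the winter labelled t.  ``normals`` gives per-point normal
    winter CMD (columns ``point, cmd_normal``).
    """
    df = climate.copy()
    winter_year = np.where(df["month"] == 12, df["year"] + 1, df["year"])
    df = df.assign(winter_year=winter_year)
    df = df[df["month"].isin([12, 1, 2])]
    cmd = (
        df.groupby(["point", "winter_year"])
        .apply(
            lambda g: compute_cmd(g["eref"].to_numpy(), g["precip"].to_numpy()),
            include_groups=False,
        )
        .unstack("winter_year")
    )
    cmd = cmd.reindex(columns=list(years))
    if cmd.isna().any().any():
        raise ValueError("winter climate samples do not cover all requested years")
    return seasonal_anomaly(cmd, normals.set_index("point")["cmd_normal"])


def spring_temperature_anomaly(
    climate: pd.DataFrame, normals: pd.DataFrame, years
) -> pd.Series:
    """Per-year spring (Feb-May) mean-temperature anomaly from point samples."""
    df = climate[climate["month"].isin([2, 3, 4, 5])]
    temp = df.groupby(["point", "year"])["temp"].mean().unstack("year")
    temp = temp.reindex(columns=list(years))
    if temp.isna().any().any():
        raise ValueError("spring climate samples do not cover all requested years")
    return seasonal_anomaly(temp, normals.set_index("point")["temp_normal"])


def standardize_covariates(series: CovariateSeries) -> CovariateSeries:
    """Z-score each covariate within stratum over years (population sd).

    The anomaly-scale columns are kept and the (mean, sd) pairs recorded so
    fitted coefficients can be back-transformed to per-anomaly-unit
    effects.  A zero-variance covariate is an error: it cannot enter a
    regression on the standardized scale.
    """
    frame = series.frame.copy()
    record: dict = {}
    for name in COVARIATE_NAMES:
        frame[f"{name}_z"] = np.nan
    for stratum, grp in frame.groupby("stratum"):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 years to standardize covariates in {stratum!r}")
        for name in COVARIATE_NAMES:
            x = grp[name].to_numpy(dtype=float)
            mu, sd = float(x.mean()), float(x.std())
            if sd == 0.0:
                raise ValueError(f"covariate {name!r} is constant in stratum {stratum!r}")
            frame.loc[grp.index, f"{name}_z"] = (x - mu) / sd
            record[(stratum, name)] = (mu, sd)
    return CovariateSeries(frame, standardization=record)


def destandardize(series: CovariateSeries, stratum, name: str, z: np.ndarray) -> np.ndarray:
    """Map z-scored values back to the anomaly scale using the stored record."""
    mu, sd = series.standardization[(stratum, name)]
    return np.asarray(z) * sd + mu
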