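"""Reading, validation and assembly of the model's tabular inputs.

The model joins four tables that arrive on different sampling frames:

* roadside point counts by route x observer x year (BBS-like), with a
  novice-observer indicator for an observer's first year on a route;
* individual capture histories of adult birds by banding station x year
  (MAPS-like), with a within-season residency observation;
* age-specific capture totals (hatch-year vs adult) by station x year with
  mist-netting effort in net-hours;
* annual climate covariates by stratum (winter drought anomaly, spring
  temperature anomaly, migration tailwind).

Everything is indexed by stratum (a breeding region) and calendar year.
Internally years are dense integers ``0..T-1`` with the first calendar year
stored once; all outputs report calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .covariates import CovariateSeries

__all__ = [
    "SchemaError",
    "ValidationError",
    "CountDataset",
    "CaptureData",
    "AgeCaptureTable",
    "StratumMeta",
    "ModelDataset",
    "load_counts",
    "load_captures",
    "load_ages",
    "load_covariate_table",
    "load_config",
    "filter_min_station_years",
    "compute_route_weights",
    "assemble_dataset",
]


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """The data violate an invariant (with offending rows named)."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Count data
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["route_observer", "route", "stratum", "year", "count", "novice"]


@dataclass
class CountDataset:
    """Route x observer x year counts with stratum labels and novice flags.

    ``records`` has columns ``route_observer, route, stratum, year, count,
    novice``.  A physical route surveyed by two observers appears as two
    route x observer units sharing one ``route`` value.  The panel may be
    unbalanced: missing (unit, year) combinations are simply absent rows.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.records, COUNT_COLUMNS, "count data")
        df = self.records
        counts = df["count"]
        bad = df.index[(counts < 0) | (counts != counts.astype(int))]
        if len(bad):
            raise ValidationError(
                f"count data: negative or non-integer counts at rows {list(bad[:10])}"
            )
        dup = df.duplicated(subset=["route_observer", "year"])
        if dup.any():
            raise ValidationError(
                "count data: duplicated (route_observer, year) rows at "
                f"{list(df.index[dup][:10])}"
            )
        first = df.groupby("route_observer")["year"].transform("min")
        bad_novice = df.index[(df["novice"] == 1) & (df["year"] != first)]
        if len(bad_novice):
            raise ValidationError(
                "count data: novice flag outside an observer's first year at rows "
                f"{list(bad_novice[:10])}"
            )
        self.records = df.reset_index(drop=True)

    # -- derived dimensions -------------------------------------------------
    @property
    def strata(self) -> list:
        return sorted(self.records["stratum"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.records["year"].min(), self.records["year"].max() + 1)

    @property
    def n_units(self) -> int:
        """Number of route x observer combinations."""
        return self.records["route_observer"].nunique()

    @property
    def calendar_year_0(self) -> int:
        return int(self.records["year"].min())

    def to_csv(self, path: str | Path) -> None:
        self.records[COUNT_COLUMNS].to_csv(path, index=False)


def load_counts(path: str | Path) -> CountDataset:
    """Read a counts CSV; recompute novice flags from first appearance if absent."""
    df = pd.read_csv(path)
    _require_columns(df, ["route_observer", "stratum", "year", "count"], "count data")
    if "route" not in df.columns:
        df["route"] = df["route_observer"]
    if "novice" not in df.columns:
        first = df.groupby("route_observer")["year"].transform("min")
        df["novice"] = (df["year"] == first).astype(int)
    return CountDataset(df[COUNT_COLUMNS].copy())


def compute_route_weights(counts: CountDataset) -> pd.Series:
    """Proportion of physical routes in each stratum with any positive count.

    This is the route-level encounter weight w_m that scales the stratum
    population index to a route-level abundance index.
    """
    out = {}
    for stratum, grp in counts.records.groupby("stratum"):
        routes = grp["route"].unique()
        if len(routes) == 0:
            raise ValidationError(f"stratum {stratum!r} has no surveyed routes")
        positive = grp.loc[grp["count"] > 0, "route"].nunique()
        out[stratum] = positive / len(routes)
    w = pd.Series(out).sort_index()
    w.name = "route_weight"
    return w


# ---------------------------------------------------------------------------
# Capture-recapture data
# ---------------------------------------------------------------------------

STATION_COLUMNS = [
    "station",
    "stratum",
    "first_year_operated",
    "last_year_operated",
    "years_operated",
]


@dataclass
class CaptureData:
    """Adult encounter histories plus a station-operation table.

    ``individuals`` holds one row per bird (individual, station, stratum,
    first_year, resident_observed) and ``detections`` is the aligned
    0/1 matrix over ``years``.  ``resident_observed`` is the within-season
    residency observation from the marking year; how it is scored from raw
    banding records is up to the data provider.
    """

    individuals: pd.DataFrame
    detections: np.ndarray
    years: np.ndarray
    stations: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(
            self.individuals,
            ["individual", "station", "stratum", "first_year", "resident_observed"],
            "capture data",
        )
        _require_columns(self.stations, STATION_COLUMNS, "station table")
        det = np.asarray(self.detections, dtype=int)
        if det.shape != (len(self.individuals), len(self.years)):
            raise ValidationError("detection matrix shape does not match individuals/years")
        if not np.isin(det, [0, 1]).all():
            raise ValidationError("detections must be 0/1")
        first_idx = np.searchsorted(self.years, self.individuals["first_year"].to_numpy())
        rows = np.arange(len(self.individuals))
        if not (det[rows, first_idx] == 1).all():
            bad = rows[det[rows, first_idx] != 1]
            raise ValidationError(f"detection absent in marking year for rows {list(bad[:10])}")
        before = np.arange(len(self.years))[None, :] < first_idx[:, None]
        if (det * before).any():
            raise ValidationError("detections before the marking year")
        r = self.individuals["resident_observed"]
        if not r.isin([0, 1]).all():
            raise ValidationError("resident_observed must be 0/1 for every individual")
        unknown = set(self.individuals["station"]) - set(self.stations["station"])
        if unknown:
            raise ValidationError(f"individuals reference unknown stations: {sorted(unknown)[:5]}")
        self.detections = det

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def to_csv(self, path: str | Path, stations_path: str | Path) -> None:
        wide = self.individuals[
            ["individual", "station", "stratum", "first_year", "resident_observed"]
        ].copy()
        for k, year in enumerate(self.years):
            wide[f"y{year}"] = self.detections[:, k]
        wide.to_csv(path, index=False)
        self.stations[STATION_COLUMNS].to_csv(stations_path, index=False)


def load_captures(path: str | Path, stations_path: str | Path) -> CaptureData:
    """Read the wide capture-history CSV and its companion station table."""
    wide = pd.read_csv(path)
    stations = pd.read_csv(stations_path)
    _require_columns(wide, ["individual", "station", "stratum", "resident_observed"], "capture data")
    year_cols = [c for c in wide.columns if c.startswith("y") and c[1:].isdigit()]
    if not year_cols:
        raise SchemaError("capture data: no per-year 0/1 columns (named y<year>) found")
    years = np.array(sorted(int(c[1:]) for c in year_cols))
    det = wide[[f"y{y}" for y in years]].to_numpy(dtype=int)
    if "first_year" in wide.columns:
        first = wide["first_year"].to_numpy()
    else:
        first = years[np.argmax(det == 1, axis=1)]
        wide = wide.assign(first_year=first)
    individuals = wide[["individual", "station", "stratum", "first_year", "resident_observed"]].copy()
    return CaptureData(individuals, det, years, stations)


def filter_min_station_years(data: CaptureData, min_years: int = 4) -> CaptureData:
    """Keep only individuals from stations operated at least ``min_years`` years.

    Mirrors the standard restriction of multi-year banding analyses to
    stations with enough operation years to inform survival.  Idempotent.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    kept_stations = data.stations.loc[
        data.stations["years_operated"] >= min_years
    ].reset_index(drop=True)
    keep = data.individuals["station"].isin(set(kept_stations["station"])).to_numpy()
    return CaptureData(
        data.individuals.loc[keep].reset_index(drop=True),
        data.detections[keep],
        data.years,
        kept_stations,
    )


# ---------------------------------------------------------------------------
# Age-specific capture data
# ---------------------------------------------------------------------------

AGE_COLUMNS = ["station", "stratum", "year", "n_hy", "n_adult", "effort_net_hours"]


@dataclass
class AgeCaptureTable:
    """Hatch-year vs adult capture totals by station-year with net-hour effort."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.rows, AGE_COLUMNS, "age-capture data")
        df = self.rows
        if (df[["n_hy", "n_adult"]] < 0).any().any():
            raise ValidationError("age-capture data: negative capture totals")
        has_caps = (df["n_hy"] + df["n_adult"]) > 0
        bad = df.index[has_caps & ~(df["effort_net_hours"] > 0)]
        if len(bad):
            raise ValidationError(
                f"age-capture data: captures with non-positive effort at rows {list(bad[:10])}"
            )
        self.rows = df.reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.rows[AGE_COLUMNS].to_csv(path, index=False)


def load_ages(path: str | Path) -> AgeCaptureTable:
    return AgeCaptureTable(pd.read_csv(path))


def load_covariate_table(path: str | Path) -> CovariateSeries:
    """Read the per-stratum annual covariate CSV (stratum, year, cmd, tw, temp)."""
    df = pd.read_csv(path)
    _require_columns(df, ["stratum", "year", "cmd", "tw", "temp"], "covariate data")
    return CovariateSeries(df)


# ---------------------------------------------------------------------------
# Stratum metadata and the assembled dataset
# ---------------------------------------------------------------------------


@dataclass
class StratumMeta:
    """Reporting weights for one stratum.

    ``area_weight`` is the proportion of total range area (composite
    abundance weights; must sum to 1 across strata); ``route_weight`` is
    the proportion of survey routes on which the species was encountered.
    """

    stratum_id: str
    name: str = ""
    area_weight: float = 1.0
    route_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.area_weight <= 1):
            raise ValidationError(f"area_weight out of (0,1] for stratum {self.stratum_id!r}")
        if not (0 < self.route_weight <= 1):
            raise ValidationError(f"route_weight out of (0,1] for stratum {self.stratum_id!r}")


@dataclass
class ModelDataset:
    """All inputs aligned on a common stratum set and year range.

    ``stratum_index`` and ``year_index`` map labels to dense 0-based
    indices; ``summary`` holds the per-stratum totals logged at assembly
    (routes, stations, individuals, recaptures).
    """

    counts: CountDataset
    captures: CaptureData
    ages: AgeCaptureTable
    covariates: CovariateSeries
    meta: list[StratumMeta]
    stratum_index: Mapping = field(default_factory=dict)
    year_index: Mapping = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    @property
    def strata(self) -> list:
        return [m.stratum_id for m in self.meta]

    @property
    def years(self) -> np.ndarray:
        return np.array(sorted(self.year_index, key=self.year_index.get))

    @property
    def n_strata(self) -> int:
        return len(self.meta)

    @property
    def n_years(self) -> int:
        return len(self.year_index)

    @property
    def area_weights(self) -> np.ndarray:
        return np.array([m.area_weight for m in self.meta])

    @property
    def route_weights(self) -> np.ndarray:
        return np.array([m.route_weight for m in self.meta])


def assemble_dataset(
    counts: CountDataset,
    captures: CaptureData,
    ages: AgeCaptureTable,
    covariates: CovariateSeries,
    meta: Sequence[StratumMeta] | None = None,
) -> ModelDataset:
    """Align all components, build dense index maps and a per-stratum summary.

    Raises an alignment error when year ranges disagree or a stratum is
    present in one source only.  When ``meta`` is omitted, route weights are
    computed from the counts and equal area weights are used.
    """
    strata = counts.strata
    for name, present in [
        ("captures", sorted(captures.individuals["stratum"].unique())),
        ("ages", sorted(ages.rows["stratum"].unique())),
        ("covariates", sorted(covariates.frame["stratum"].unique())),
    ]:
        # empty components are allowed (e.g. count-only fits); non-empty ones
        # must cover exactly the strata of the counts
        if present and present != strata:
            raise ValidationError(
                f"stratum mismatch between counts {strata} and {name} {present}"
            )
    years = counts.years
    cov_years = covariates.frame["year"]
    if cov_years.min() > years.min() or cov_years.max() < years.max():
        raise ValidationError(
            f"covariates span {cov_years.min()}-{cov_years.max()} but counts span "
            f"{years.min()}-{years.max()}"
        )
    if not set(captures.years).issubset(set(years)):
        raise ValidationError("capture-history years extend beyond the count years")
    if meta is None:
        w = compute_route_weights(counts)
        meta = [
            StratumMeta(s, area_weight=1.0 / len(strata), route_weight=max(w[s], 1e-12))
            for s in strata
        ]
    meta = list(meta)
    if sorted(m.stratum_id for m in meta) != strata:
        raise ValidationError("stratum metadata does not cover the data's strata")
    total_area = sum(m.area_weight for m in meta)
    if abs(total_area - 1.0) > 1e-6:
        raise ValidationError(f"area weights sum to {total_area}, expected 1")
    meta.sort(key=lambda m: strata.index(m.stratum_id))

    stratum_index = {s: k for k, s in enumerate(strata)}
    year_index = {int(y): k for k, y in enumerate(years)}

    det = captures.detections
    first_idx = np.searchsorted(captures.years, captures.individuals["first_year"].to_numpy())
    recaps = np.zeros(len(det), dtype=int)
    for j in range(len(det)):
        recaps[j] = det[j, first_idx[j] + 1 :].sum()
    ind = captures.individuals.assign(_recaps=recaps)
    summary = pd.DataFrame(
        {
            "n_routes": counts.records.groupby("stratum")["route"].nunique(),
            "birds_per_route": counts.records.groupby("stratum")["count"].mean(),
            "n_age_stations": ages.rows.groupby("stratum")["station"].nunique(),
            "n_hy": ages.rows.groupby("stratum")["n_hy"].sum(),
            "n_adult": ages.rows.groupby("stratum")["n_adult"].sum(),
            "n_cmr_stations": captures.stations.groupby("stratum")["station"].nunique(),
            "n_individuals": ind.groupby("stratum")["individual"].nunique(),
            "n_recaptures": ind.groupby("stratum")["_recaps"].sum(),
        }
    ).reindex(strata)

    return ModelDataset(
        counts=counts,
        captures=captures,
        ages=ages,
        covariates=covariates,
        meta=meta,
        stratum_index=stratum_index,
        year_index=year_index,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load the single YAML config naming paths, year range, strata and MCMC settings."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    return cfg


def load_dataset_from_config(path: str | Path) -> ModelDataset:
    """Convenience loader: read all four tables named in a YAML config and assemble."""
    cfg = load_config(path)
    base = Path(path).parent
    paths = cfg["paths"]
    counts = load_counts(base / paths["counts"])
    captures = load_captures(base / paths["captures"], base / paths["stations"])
    if cfg.get("min_station_years"):
        captures = filter_min_station_years(captures, int(cfg["min_station_years"]))
    ages = load_ages(base / paths["ages"])
    covariates = load_covariate_table(base / paths["covariates"])
    meta = None
    if "strata" in cfg:
        meta = [
            StratumMeta(
                s["id"],
                name=s.get("name", ""),
                area_weight=s["area_weight"],
                route_weight=s.get("route_weight", 1.0),
            )
            for s in cfg["strata"]
        ]
    return assemble_dataset(counts, captures, ages, covariates, meta)
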