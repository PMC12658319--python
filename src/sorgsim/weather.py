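"""Weather and field-trial table I/O, validation and kNN gap-filling.

Hourly weather follows the Iowa Environmental Mesonet station schema: air
temperature, relative humidity, solar radiation, precipitation, wind speed,
evapotranspiration, soil temperature at four depths and soil volumetric water
content at three depths.  A :class:`WeatherSeries` wraps a strictly hourly
:class:`pandas.DataFrame` in which ``NaN`` marks a missing cell; gaps in the
timestamp axis are materialized as all-missing rows, never silently skipped.

Missing cells are filled with a k-nearest-neighbours imputer: neighbours are
other hourly records that are fully observed, distance is Euclidean over
z-scored fields observed in the target record plus sin/cos-encoded hour-of-day
and day-of-year (so diurnal and seasonal structure informs the neighbourhood),
ties break toward the earlier timestamp, and each missing value becomes the
mean of its k nearest complete neighbours.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: Weather fields, in canonical column order (timestamp is the index).
WEATHER_FIELDS = (
    "air_temp",
    "rel_humidity",
    "solar_radiation",
    "precipitation",
    "wind_speed",
    "evapotranspiration",
    "soil_temp_4in",
    "soil_temp_12in",
    "soil_temp_24in",
    "soil_temp_50in",
    "soil_vwc_12in",
    "soil_vwc_24in",
    "soil_vwc_50in",
)

#: Physical validity ranges; cells outside become missing on import.
FIELD_RANGES: Dict[str, tuple] = {
    "air_temp": (-60.0, 60.0),
    "rel_humidity": (0.0, 100.0),
    "solar_radiation": (0.0, 1500.0),
    "precipitation": (0.0, 500.0),
    "wind_speed": (0.0, 80.0),
    "evapotranspiration": (0.0, 50.0),
    "soil_temp_4in": (-40.0, 55.0),
    "soil_temp_12in": (-40.0, 55.0),
    "soil_temp_24in": (-40.0, 55.0),
    "soil_temp_50in": (-40.0, 55.0),
    "soil_vwc_12in": (0.0, 1.0),
    "soil_vwc_24in": (0.0, 1.0),
    "soil_vwc_50in": (0.0, 1.0),
}


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


class ImputationError(ValueError):
    """Raised when kNN imputation cannot proceed."""


@dataclass
class ImportReport:
    """Per-field counts of cells flagged missing during import."""

    unparseable: Dict[str, int] = field(default_factory=dict)
    out_of_range: Dict[str, int] = field(default_factory=dict)
    gap_rows: int = 0

    @property
    def total_flagged(self) -> int:
        return sum(self.unparseable.values()) + sum(self.out_of_range.values())


@dataclass
class WeatherSeries:
    """One station's hourly weather for (at least) a growing season."""

    data: pd.DataFrame
    station_id: str = "synthetic"
    latitude: float = 42.0
    import_report: ImportReport = field(default_factory=ImportReport)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != list(WEATHER_FIELDS):
            df = df.reindex(columns=list(WEATHER_FIELDS))
        idx = pd.DatetimeIndex(df.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            bad = list(np.flatnonzero(np.diff(idx.view("i8")) <= 0)[:10])
            raise SchemaError(f"timestamps not strictly increasing at rows {bad}")
        full = pd.date_range(idx[0], idx[-1], freq="h")
        if len(full) != len(idx) or not (full == idx).all():
            df = df.reindex(full)  # gaps become all-missing rows
        df.index.name = "timestamp"
        self.data = df.astype(float)

    # -- basic queries ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def covers(self, mgmt: "ManagementRecord") -> bool:
        start, end = self.data.index[0], self.data.index[-1]
        return (start.date() <= mgmt.planting_date
                and end.date() >= mgmt.harvest_date)

    def slice_days(self, start: dt.date, end: dt.date) -> "WeatherSeries":
        """Sub-series covering [start, end] whole days (inclusive)."""
        lo = pd.Timestamp(start)
        hi = pd.Timestamp(end) + pd.Timedelta(hours=23)
        return WeatherSeries(self.data.loc[lo:hi].copy(),
                             station_id=self.station_id,
                             latitude=self.latitude)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="timestamp")


@dataclass(frozen=True)
class ManagementRecord:
    """Season management: dates, stand density and row spacing."""

    planting_date: dt.date
    harvest_date: dt.date
    stand_count: float  # plants/m^2
    row_spacing: float = 70.0  # cm

    def __post_init__(self) -> None:
        if self.harvest_date <= self.planting_date:
            raise ValueError("harvest_date must be after planting_date")
        if self.stand_count <= 0:
            raise ValueError("stand_count must be positive")

    @property
    def season_days(self) -> int:
        return (self.harvest_date - self.planting_date).days


@dataclass(frozen=True)
class TrialObservation:
    """One observed (genotype, year, block, day) biomass record, g/plant."""

    genotype_id: str
    year: int
    block: int
    stand_count: float
    day_after_planting: int
    leaf_dry_biomass: float
    stem_dry_biomass: float

    def __post_init__(self) -> None:
        if self.leaf_dry_biomass < 0 or self.stem_dry_biomass < 0:
            raise ValueError("dry biomass must be non-negative")
        if self.day_after_planting <= 0:
            raise ValueError("day_after_planting must be positive")
        if self.stand_count <= 0:
            raise ValueError("stand_count must be positive")


DEFAULT_SCHEMA: Dict[str, str] = {f: f for f in WEATHER_FIELDS}
DEFAULT_SCHEMA["timestamp"] = "timestamp"


def load_schema(path) -> Dict[str, str]:
    """Load a field -> column-name map from a YAML/JSON config file."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if "timestamp" not in schema:
        raise SchemaError("schema must map a 'timestamp' column")
    return schema


def read_weather_csv(
    path,
    schema: Optional[Dict[str, str]] = None,
    station_id: str = "",
    latitude: float = 42.0,
) -> WeatherSeries:
    """Read an hourly weather CSV, flagging bad cells as missing.

    Unparseable or physically out-of-range cells become ``NaN`` and are
    counted in the series' :class:`ImportReport`.  Raises
    :class:`SchemaError` if the timestamp column is absent or non-monotone.
    """
    schema = dict(schema or DEFAULT_SCHEMA)
    ts_col = schema.pop("timestamp", "timestamp")
    raw = pd.read_csv(path, dtype=str)
    if ts_col not in raw.columns:
        raise SchemaError(f"timestamp column {ts_col!r} not found")
    try:
        ts = pd.to_datetime(raw[ts_col], format="mixed")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"unparseable timestamps: {exc}") from exc
    if ts.isna().any():
        raise SchemaError(
            f"unparseable timestamps at rows {list(np.flatnonzero(ts.isna())[:10])}"
        )
    order = np.diff(ts.values.astype("datetime64[ns]").astype("i8"))
    if (order <= 0).any():
        raise SchemaError(
            f"timestamps not strictly increasing at rows "
            f"{list(np.flatnonzero(order <= 0)[:10])}"
        )

    report = ImportReport()
    cols = {}
    for fld in WEATHER_FIELDS:
        col = schema.get(fld)
        if col is None or col not in raw.columns:
            cols[fld] = np.full(len(raw), np.nan)
            continue
        numeric = pd.to_numeric(raw[col], errors="coerce")
        n_unparseable = int((numeric.isna() & raw[col].notna()
                             & (raw[col].str.strip() != "")).sum())
        if n_unparseable:
            report.unparseable[fld] = n_unparseable
        lo, hi = FIELD_RANGES[fld]
        bad = numeric.notna() & ((numeric < lo) | (numeric > hi))
        if bad.any():
            report.out_of_range[fld] = int(bad.sum())
            numeric = numeric.mask(bad)
        cols[fld] = numeric.to_numpy(dtype=float)
    df = pd.DataFrame(cols, index=pd.DatetimeIndex(ts))
    series = WeatherSeries(df, station_id=station_id, latitude=latitude)
    report.gap_rows = len(series) - len(raw)
    series.import_report = report
    return series


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """Z-scored field values alongside cyclic hour/day-of-year encodings."""
    vals = df.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=0)
    std = np.nanstd(vals, axis=0)
    std[std == 0] = 1.0
    z = (vals - mean) / std
    idx = pd.DatetimeIndex(df.index)
    hour = idx.hour.to_numpy() / 24.0
    doy = idx.dayofyear.to_numpy() / 365.25
    time_feats = np.column_stack([
        np.sin(2 * np.pi * hour), np.cos(2 * np.pi * hour),
        np.sin(2 * np.pi * doy), np.cos(2 * np.pi * doy),
    ])
    return np.hstack([z, time_feats])


def impute_missing_knn(series: WeatherSeries, k: int = 5) -> WeatherSeries:
    """Fill every missing cell with the mean over the k nearest complete rows.

    Deterministic: neighbour ties break toward the earlier timestamp.
    Observed cells are never altered.  Raises :class:`ImputationError` if a
    field is missing everywhere or fewer than ``k`` complete rows exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = series.data
    if not df.isna().any().any():
        return series

    all_missing = [c for c in WEATHER_FIELDS if df[c].isna().all()]
    if all_missing:
        raise ImputationError(
            f"cannot impute fields missing everywhere: {all_missing}"
        )
    nan_mask = df.isna().to_numpy()
    complete = ~nan_mask.any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < k:
        raise ImputationError(
            f"need at least k={k} fully observed records, have {n_complete}"
        )

    feats = _feature_matrix(df)
    n_fields = len(WEATHER_FIELDS)
    comp_idx = np.flatnonzero(complete)
    comp_feats = feats[comp_idx]
    values = df.to_numpy(dtype=float).copy()
    comp_values = values[comp_idx]

    for i in np.flatnonzero(nan_mask.any(axis=1)):
        observed = ~nan_mask[i]
        sel = np.concatenate([observed, np.ones(4, dtype=bool)])
        diffs = comp_feats[:, sel] - feats[i, sel]
        dists = np.einsum("ij,ij->i", diffs, diffs)
        # stable sort on (distance, original row index) => earlier-timestamp ties
        order = np.lexsort((comp_idx, dists))[:k]
        neigh = comp_values[order]
        for j in np.flatnonzero(nan_mask[i][:n_fields]):
            values[i, j] = neigh[:, j].mean()

    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    return WeatherSeries(out, station_id=series.station_id,
                         latitude=series.latitude)


# -- field-trial phenotype tables ---------------------------------------

TRIAL_COLUMNS = (
    "genotype_id", "year", "block", "stand_count",
    "day_after_planting", "leaf_dry_biomass", "stem_dry_biomass",
)


def read_trial_table(path) -> List[TrialObservation]:
    """Read a field-trial phenotype CSV into validated observations."""
    df = pd.read_csv(path, dtype={"genotype_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial table missing columns: {sorted(missing)}")
    bad = df.index[(df["leaf_dry_biomass"] < 0) | (df["stem_dry_biomass"] < 0)]
    if len(bad):
        raise ValueError(f"negative biomass at rows {list(bad[:20])}")
    return [
        TrialObservation(
            genotype_id=str(r.genotype_id),
            year=int(r.year),
            block=int(r.block),
            stand_count=float(r.stand_count),
            day_after_planting=int(r.day_after_planting),
            leaf_dry_biomass=float(r.leaf_dry_biomass),
            stem_dry_biomass=float(r.stem_dry_biomass),
        )
        for r in df.itertuples(index=False)
    ]


def write_trial_table(observations: Sequence[TrialObservation], path) -> None:
    """Write observations to CSV; read_trial_table round-trips losslessly."""
    df = pd.DataFrame([dataclasses.asdict(o) for o in observations],
                      columns=list(TRIAL_COLUMNS))
    df.to_csv(path, index=False)


def trial_series(observations: Sequence[TrialObservation]):
    """Group observations into per-(genotype, year, block) sorted series."""
    groups: Dict[tuple, List[TrialObservation]] = {}
    for obs in observations:
        groups.setdefault((obs.genotype_id, obs.year, obs.block), []).append(obs)
    return {
        key: sorted(group, key=lambda o: o.day_after_planting)
        for key, group in sorted(groups.items())
    }
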