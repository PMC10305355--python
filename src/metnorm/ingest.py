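"""Readers, daily aggregation, and feature-table construction.

The canonical on-disk interchange formats are two tidy CSV schemas:

* pollutant CSV: header ``date,hour,pollutant,value`` (``hour`` empty for a
  daily series), ISO-8601 dates, empty field = missing;
* met CSV: header ``date,u10,v10,t,blh,sr,sp,tcc,tp,rh,u500,v500,w500,u850,
  v850,w850`` with one row per day.

The random-forest feature table has exactly three time features (unix_time,
julian_day, weekday) plus fourteen meteorological features; sea-level
pressure (``sp``) is carried in the met CSV but excluded from the default
feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical pollutant ids and concentration units.
POLLUTANT_UNITS = {
    "PM2.5": "ug m-3",
    "PM10": "ug m-3",
    "NO2": "ug m-3",
    "SO2": "ug m-3",
    "O3": "ug m-3",
    "CO": "mg m-3",
}

#: Fixed tie-break / presentation order.
POLLUTANT_ORDER = ("PM2.5", "PM10", "O3", "NO2", "SO2", "CO")

#: Meteorological features used by the deweathering model, in column order.
MET_FEATURES = (
    "u10", "v10", "t", "blh", "sr", "tcc", "tp", "rh",
    "u500", "v500", "w500", "u850", "v850", "w850",
)

#: Met CSV columns (sp is stored but not a default model feature).
MET_CSV_COLUMNS = (
    "u10", "v10", "t", "blh", "sr", "sp", "tcc", "tp", "rh",
    "u500", "v500", "w500", "u850", "v850", "w850",
)

TIME_FEATURES = ("unix_time", "julian_day", "weekday")


@dataclass
class PollutantSeries:
    """A timestamped concentration series for one pollutant.

    ``data`` is a float Series with a DatetimeIndex (strictly increasing);
    NaN marks missing values. ``basis`` is ``"hourly"`` or ``"daily"``.
    """

    pollutant: str
    data: pd.Series
    basis: str = "daily"

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANT_UNITS:
            raise ValueError(f"unknown pollutant id: {self.pollutant!r}")
        if self.basis not in ("hourly", "daily"):
            raise ValueError(f"basis must be 'hourly' or 'daily', got {self.basis!r}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("PollutantSeries.data must have a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        valid = self.data.dropna()
        if (valid < 0).any():
            raise ValueError("concentrations must be >= 0 or missing")

    @property
    def units(self) -> str:
        return POLLUTANT_UNITS[self.pollutant]

    def __len__(self) -> int:
        return len(self.data)


def read_pollutant_csv(path, pollutant: str, max_bad_fraction: float = 0.05) -> PollutantSeries:
    """Read a tidy pollutant CSV into a :class:`PollutantSeries`.

    Negative concentrations are converted to missing (with a logged count);
    rows are sorted by timestamp. If more than ``max_bad_fraction`` of the
    rows for the requested pollutant fail to parse, a ``ValueError`` is
    raised.
    """
    if pollutant not in POLLUTANT_UNITS:
        raise ValueError(f"unknown pollutant id: {pollutant!r}")
    raw = pd.read_csv(path, dtype={"date": str, "hour": "Int64", "pollutant": str})
    expected = {"date", "hour", "pollutant", "value"}
    if not expected.issubset(raw.columns):
        raise ValueError(f"pollutant CSV must have columns {sorted(expected)}")
    raw = raw[raw["pollutant"] == pollutant]
    if raw.empty:
        raise ValueError(f"no rows for pollutant {pollutant!r} in {path}")

    dates = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad > max_bad_fraction * len(raw):
        raise ValueError(f"{n_bad}/{len(raw)} unparseable rows in {path}")
    raw = raw[dates.notna()]
    dates = dates[dates.notna()]

    hourly = raw["hour"].notna().any()
    if hourly:
        stamps = dates + pd.to_timedelta(raw["hour"].fillna(0).astype(int), unit="h")
    else:
        stamps = dates
    values = pd.to_numeric(raw["value"], errors="coerce")
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.warning("%s: %d negative value(s) set to missing", pollutant, n_neg)
        values = values.where(values >= 0)

    series = pd.Series(values.to_numpy(), index=pd.DatetimeIndex(stamps), name=pollutant)
    series = series[~series.index.duplicated(keep="first")].sort_index()
    return PollutantSeries(pollutant, series, basis="hourly" if hourly else "daily")


def write_pollutant_csv(series: PollutantSeries, path) -> None:
    """Write a series in the canonical ``date,hour,pollutant,value`` schema."""
    idx = series.data.index
    frame = pd.DataFrame(
        {
            "date": idx.strftime("%Y-%m-%d"),
            "hour": idx.hour if series.basis == "hourly" else "",
            "pollutant": series.pollutant,
            "value": series.data.to_numpy(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.6g")


def read_met_csv(path) -> pd.DataFrame:
    """Read a daily met CSV into a date-indexed DataFrame."""
    frame = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in MET_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"met CSV missing columns: {missing}")
    frame = frame.set_index("date").sort_index()
    return frame[list(MET_CSV_COLUMNS)].astype(float)


def write_met_csv(met: pd.DataFrame, path) -> None:
    out = met.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.8g")


def read_met_netcdf(path, lon: float, lat: float) -> pd.DataFrame:
    """Extract the grid cell nearest (lon, lat) from a CF-convention NetCDF
    file of daily met fields. Convenience only — CSV is canonical."""
    import xarray as xr  # optional heavy dependency, imported lazily

    ds = xr.open_dataset(path)
    lon_name = "longitude" if "longitude" in ds.coords else "lon"
    lat_name = "latitude" if "latitude" in ds.coords else "lat"
    point = ds.sel({lon_name: lon, lat_name: lat}, method="nearest")
    frame = point.to_dataframe()
    frame.index = pd.DatetimeIndex(frame.index.get_level_values("time")
                                   if "time" in frame.index.names else frame.index)
    frame.columns = [c.lower() for c in frame.columns]
    return frame


def daily_average(series: PollutantSeries, min_coverage: float = 0.75,
                  metric: str = "mean") -> PollutantSeries:
    """Aggregate an hourly series to daily values.

    ``metric="mean"`` gives the arithmetic daily mean; a day with fewer than
    ``min_coverage`` × 24 valid hours is missing. ``metric="max8h"`` gives
    the maximum daily 8-h running mean (for ozone), with the same coverage
    rule applied to each 8-h window (≥ 75% of 8 hours valid).
    """
    if series.basis != "hourly":
        raise ValueError("daily_average requires an hourly series")
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    data = series.data
    if metric == "mean":
        by_day = data.groupby(data.index.normalize())
        means = by_day.mean()
        counts = by_day.count()
        daily = means.where(counts >= min_coverage * 24)
    elif metric == "max8h":
        rolled = data.rolling("8h", min_periods=6).mean()
        daily = rolled.groupby(rolled.index.normalize()).max()
    else:
        raise ValueError(f"unknown daily metric {metric!r}")
    daily = daily.dropna()
    daily.index = pd.DatetimeIndex(daily.index)
    return PollutantSeries(series.pollutant, daily, basis="daily")


def unix_time(dates: pd.DatetimeIndex) -> np.ndarray:
    """Seconds since 1970-01-01 treating local midnight as UTC midnight."""
    return (dates.asi8 // 10**9).astype(np.int64)


def build_features(met: pd.DataFrame, dates, target: pd.Series | None = None,
                   include_sp: bool = False) -> pd.DataFrame:
    """Assemble the model feature table for ``dates``.

    Columns: the three time features, the fourteen met features (plus ``sp``
    when requested), a boolean ``complete`` flag (False where any met value
    is missing) and, if given, the aligned ``target`` concentration.
    Weekday is integer-coded Monday=0 … Sunday=6.
    """
    dates = pd.DatetimeIndex(dates)
    missing_days = dates.difference(met.index)
    if len(missing_days):
        raise ValueError(f"{len(missing_days)} requested day(s) outside met coverage, "
                         f"first: {missing_days[0].date()}")
    met_cols = list(MET_FEATURES) + (["sp"] if include_sp else [])
    table = pd.DataFrame(index=dates)
    table["unix_time"] = unix_time(dates)
    table["julian_day"] = dates.dayofyear
    table["weekday"] = dates.dayofweek
    for col in met_cols:
        table[col] = met.loc[dates, col].to_numpy()
    table["complete"] = table[met_cols].notna().all(axis=1)
    if target is not None:
        table["target"] = target.reindex(dates).to_numpy()
    return table


@dataclass
class Climatology:
    """The historical daily met record used as the weather resampling pool."""

    met: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.met.index, pd.DatetimeIndex):
            raise TypeError("climatology must be date-indexed")
        self.met = self.met.sort_index()

    @classmethod
    def from_met(cls, met: pd.DataFrame, fill_missing: bool = True) -> "Climatology":
        """Build a gap-free pool; gaps are filled with calendar-day
        climatological means (mean over years of the same month/day)."""
        met = met.sort_index()
        if fill_missing and met.isna().any().any():
            key = list(zip(met.index.month, met.index.day))
            clim_means = met.groupby([met.index.month, met.index.day]).transform("mean")
            met = met.fillna(clim_means)
            if met.isna().any().any():
                raise ValueError("climatology has calendar days with no data at all")
            del key
        return cls(met)

    @property
    def period(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.met.index[0], self.met.index[-1]

    def covers(self, start, end) -> bool:
        lo, hi = self.period
        return lo <= pd.Timestamp(start) and pd.Timestamp(end) <= hi

    def __len__(self) -> int:
        return len(self.met)
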