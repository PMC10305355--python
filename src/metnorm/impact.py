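"""Meteorological impact index and emission-vs-meteorology trend attribution.

The MET impact index for an averaging unit i (usually a month) is

    index_i = (C_obs,i − C_dew,i) / C_obs,i

Positive values mean meteorology pushed concentrations above the
emission-driven (deweathered) level — adverse weather; negative values mean
favorable weather. Long-term trends are OLS slopes of annual means; the
emission contribution to an observed trend is the ratio of the deweathered
to the observed slope, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WARM_MONTHS = (4, 5, 6, 7, 8, 9)
COLD_MONTHS = (10, 11, 12, 1, 2, 3)


def met_impact_index(observed, deweathered):
    """(observed − deweathered) / observed; scalar or elementwise.

    Requires observed > 0. Zero when the deweathered mean equals the
    observed mean; strictly below 1 for positive concentrations.
    """
    obs = np.asarray(observed, float)
    dew = np.asarray(deweathered, float)
    if np.any(obs <= 0):
        raise ValueError("met_impact_index requires observed > 0")
    out = (obs - dew) / obs
    return float(out) if out.ndim == 0 else out


def annual_means(daily: pd.Series) -> pd.Series:
    """Arithmetic mean of daily values per calendar year (NaN-skipping);
    years with no valid day are absent from the result."""
    clean = daily.dropna()
    means = clean.groupby(clean.index.year).mean()
    means.index.name = "year"
    return means


def monthly_means(daily: pd.Series) -> pd.Series:
    """Mean per (year, month), indexed by a MultiIndex."""
    clean = daily.dropna()
    out = clean.groupby([clean.index.year, clean.index.month]).mean()
    out.index.names = ["year", "month"]
    return out


@dataclass(frozen=True)
class TrendEstimate:
    """OLS slope of annual means on year, with its standard error."""

    pollutant: str
    start_year: int
    end_year: int
    slope: float          # concentration units per year
    stderr: float
    n_years: int


def fit_trend(annual: pd.Series, period: tuple[int, int] | None = None,
              pollutant: str = "") -> TrendEstimate:
    """Ordinary-least-squares trend of annual means over an inclusive period."""
    if period is not None:
        annual = annual.loc[(annual.index >= period[0]) & (annual.index <= period[1])]
    annual = annual.dropna()
    if len(annual) < 3:
        raise ValueError(f"need >= 3 years for a trend, got {len(annual)}")
    years = annual.index.to_numpy(float)
    res = stats.linregress(years, annual.to_numpy(float))
    return TrendEstimate(
        pollutant=pollutant,
        start_year=int(years.min()),
        end_year=int(years.max()),
        slope=float(res.slope),
        stderr=float(res.stderr),
        n_years=len(annual),
    )


def emission_contribution(deweathered_slope: float, observed_slope: float) -> int | None:
    """Emission share of the observed trend: 100 × deweathered/observed,
    rounded half-up to the nearest integer percent.

    Returns None (flagged undefined) when the slopes disagree in sign;
    raises when the observed slope is zero.
    """
    if not (np.isfinite(deweathered_slope) and np.isfinite(observed_slope)):
        raise ValueError("slopes must be finite")
    if observed_slope == 0:
        raise ZeroDivisionError("observed slope is zero; contribution undefined")
    if deweathered_slope * observed_slope < 0:
        return None
    pct = 100.0 * deweathered_slope / observed_slope
    return int(np.floor(pct + 0.5))


def covid_adjust(daily: pd.Series) -> pd.Series:
    """Sensitivity series with 2020 replaced by 2019, calendar day by
    calendar day (Feb 29 takes Feb 28); all other years untouched."""
    years = daily.index.year
    if 2019 not in years:
        raise ValueError("covid_adjust requires 2019 data")
    if 2020 not in years:
        raise ValueError("covid_adjust requires 2020 data")
    donor = daily[years == 2019]
    donor_by_md = {(ts.month, ts.day): v for ts, v in donor.items()}
    out = daily.copy()
    for ts in daily.index[years == 2020]:
        md = (ts.month, ts.day) if (ts.month, ts.day) != (2, 29) else (2, 28)
        out.loc[ts] = donor_by_md.get(md, np.nan)
    return out


# ---------------------------------------------------------------------------
# MET impact aggregations


def met_impact_by_month(observed: pd.Series, deweathered: pd.Series) -> pd.DataFrame:
    """Monthly-climatology MET impact index.

    The index is computed per (year, month) from monthly means, then
    averaged per calendar month across years; ``sd`` is the across-year
    standard deviation (the error bar).
    """
    obs_m = monthly_means(observed)
    dew_m = monthly_means(deweathered).reindex(obs_m.index)
    idx = pd.Series(met_impact_index(obs_m.to_numpy(), dew_m.to_numpy()),
                    index=obs_m.index)
    grouped = idx.groupby(level="month")
    out = pd.DataFrame({"met_impact_index": grouped.mean(), "sd": grouped.std(ddof=1)})
    out.index.name = "month"
    return out


def met_impact_by_season(observed: pd.Series, deweathered: pd.Series) -> pd.DataFrame:
    """Warm-season (Apr–Sep) vs cold-season (Oct–Mar) MET impact index,
    computed per (year, season) then averaged across years."""

    def season(month: int) -> str:
        return "warm" if month in WARM_MONTHS else "cold"

    rows = []
    for series, name in ((observed, "obs"), (deweathered, "dew")):
        clean = series.dropna()
        grp = clean.groupby([clean.index.year,
                             clean.index.month.map(season)]).mean()
        grp.index.names = ["year", "season"]
        rows.append(grp.rename(name))
    merged = pd.concat(rows, axis=1).dropna()
    idx = pd.Series(met_impact_index(merged["obs"].to_numpy(),
                                     merged["dew"].to_numpy()),
                    index=merged.index)
    grouped = idx.groupby(level="season")
    out = pd.DataFrame({"met_impact_index": grouped.mean(), "sd": grouped.std(ddof=1)})
    out.index.name = "season"
    return out


def met_impact_period(observed: pd.Series, deweathered: pd.Series,
                      period: tuple[int, int]) -> tuple[float, float]:
    """Period-level MET impact index from period-mean observed and
    deweathered concentrations; the second value is the standard deviation
    of the yearly indexes (the error bar)."""
    lo, hi = period
    mask_o = (observed.index.year >= lo) & (observed.index.year <= hi)
    mask_d = (deweathered.index.year >= lo) & (deweathered.index.year <= hi)
    obs, dew = observed[mask_o].dropna(), deweathered[mask_d].dropna()
    if obs.empty:
        raise ValueError(f"no observed data in {period}")
    value = met_impact_index(obs.mean(), dew.mean())
    yearly = met_impact_index(annual_means(obs).to_numpy(),
                              annual_means(dew).reindex(annual_means(obs).index).to_numpy())
    return float(value), float(np.std(yearly, ddof=1)) if len(yearly) > 1 else float("nan")


DEFAULT_PERIODS = ((2015, 2022), (2015, 2018), (2019, 2022))


def trend_table(observed: pd.Series, deweathered: pd.Series, pollutant: str = "",
                periods=DEFAULT_PERIODS) -> pd.DataFrame:
    """Tidy per-period trends and emission contributions for one pollutant.

    Columns: pollutant, period, observed_slope, observed_se,
    deweathered_slope, deweathered_se, contribution_pct (empty when the
    slopes disagree in sign).
    """
    obs_ann = annual_means(observed)
    dew_ann = annual_means(deweathered)
    rows = []
    for period in periods:
        t_obs = fit_trend(obs_ann, period, pollutant)
        t_dew = fit_trend(dew_ann, period, pollutant)
        try:
            contrib = emission_contribution(t_dew.slope, t_obs.slope)
        except ZeroDivisionError:
            contrib = None
        rows.append(
            {
                "pollutant": pollutant,
                "period": f"{period[0]}-{period[1]}",
                "observed_slope": t_obs.slope,
                "observed_se": t_obs.stderr,
                "deweathered_slope": t_dew.slope,
                "deweathered_se": t_dew.stderr,
                "contribution_pct": contrib,
            }
        )
    return pd.DataFrame(rows)
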