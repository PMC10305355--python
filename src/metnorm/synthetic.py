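"""Synthetic daily meteorology and pollutant series with known ground truth.

Every downstream stage (deweathering, trend attribution, health risk,
mortality) is validated against data generated here, where the emission
trend and the weather response are known exactly:

    observed(day) = emission(day) * weather_factor(met(day)) * noise(day)

with ``emission = baseline * trend_factor * weekday_factor``. The generator
records each factor so reconstruction is exact and parameter recovery can be
scored against truth rather than against another model.

Meteorological variables are a seasonal sinusoid plus an AR(1) anomaly
(day-to-day autocorrelation matters: the resampling step downstream must
face realistic persistence, not white noise) plus an optional secular drift,
which is what creates weather-confounded trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import (
    MET_CSV_COLUMNS,
    Climatology,
    PollutantSeries,
    build_features,
)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SeasonalVariable:
    """One met variable: seasonal cycle + AR(1) anomaly + optional drift.

    value(d) = mean + amplitude*cos(2π(doy-peak_doy)/365.25)
             + trend_per_year*(years since period midpoint) + AR(1) anomaly

    ``sigma`` is the AR(1) innovation standard deviation; ``rho`` in [0, 1).
    ``lower``/``upper`` clip physically bounded variables (cloud fraction to
    [0, 1], relative humidity to [0, 100], and so on).
    """

    mean: float
    amplitude: float = 0.0
    peak_doy: float = 196.0
    rho: float = 0.0
    sigma: float = 0.0
    trend_per_year: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        vals = [self.mean, self.amplitude, self.peak_doy, self.rho,
                self.sigma, self.trend_per_year]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite value in SeasonalVariable config")
        if not 0 <= self.rho < 1:
            raise ValueError(f"AR(1) coefficient must be in [0, 1), got {self.rho}")
        if self.sigma < 0 or self.amplitude < 0:
            raise ValueError("sigma and amplitude must be >= 0")


def default_met_variables() -> dict[str, SeasonalVariable]:
    """Plausible mid-latitude coastal defaults for the 15 stored variables
    (native ERA5-style units: T in K, BLH in m, SR in J m⁻² day⁻¹, SP in Pa,
    TP in m day⁻¹, TCC as a fraction, RH in %, winds in m s⁻¹)."""
    return {
        "u10": SeasonalVariable(2.0, 1.0, peak_doy=196, rho=0.6, sigma=0.8),
        "v10": SeasonalVariable(0.5, 1.0, peak_doy=15, rho=0.6, sigma=0.8),
        "t": SeasonalVariable(288.0, 11.0, peak_doy=200, rho=0.8, sigma=1.5),
        "blh": SeasonalVariable(500.0, 150.0, peak_doy=150, rho=0.7, sigma=60.0, lower=50.0),
        "sr": SeasonalVariable(1.5e7, 8.0e6, peak_doy=172, rho=0.5, sigma=2.0e6, lower=0.0),
        "sp": SeasonalVariable(101325.0, 800.0, peak_doy=15, rho=0.8, sigma=300.0),
        "tcc": SeasonalVariable(0.5, 0.15, peak_doy=196, rho=0.5, sigma=0.15,
                                lower=0.0, upper=1.0),
        "tp": SeasonalVariable(0.003, 0.002, peak_doy=196, rho=0.3, sigma=0.003, lower=0.0),
        "rh": SeasonalVariable(70.0, 10.0, peak_doy=196, rho=0.7, sigma=6.0,
                               lower=0.0, upper=100.0),
        "u500": SeasonalVariable(10.0, 8.0, peak_doy=15, rho=0.8, sigma=3.0),
        "v500": SeasonalVariable(1.0, 2.0, peak_doy=15, rho=0.7, sigma=2.0),
        "w500": SeasonalVariable(0.0, 0.05, peak_doy=196, rho=0.5, sigma=0.05),
        "u850": SeasonalVariable(4.0, 4.0, peak_doy=15, rho=0.7, sigma=2.0),
        "v850": SeasonalVariable(1.0, 2.0, peak_doy=196, rho=0.7, sigma=1.5),
        "w850": SeasonalVariable(0.0, 0.05, peak_doy=196, rho=0.5, sigma=0.05),
    }


@dataclass(frozen=True)
class SyntheticMetConfig:
    start_date: str
    end_date: str
    variables: dict[str, SeasonalVariable] = field(default_factory=default_met_variables)
    seed: int = 0

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError("end_date must be after start_date")


def generate_met(config: SyntheticMetConfig) -> pd.DataFrame:
    """Generate one row per day from start to end inclusive.

    Drift is referenced to the midpoint of the generated period so the
    period-mean of a drifting variable stays at its configured mean. The
    same seed always produces a bit-identical table.
    """
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    years = (dates - dates[0]).days.to_numpy(float) / DAYS_PER_YEAR
    years_mid = years - years.mean()
    rng = np.random.default_rng(config.seed)

    out = pd.DataFrame(index=dates)
    # fixed column order so the rng stream is reproducible regardless of
    # dict insertion order in user configs
    for name in MET_CSV_COLUMNS:
        if name not in config.variables:
            continue
        var = config.variables[name]
        seasonal = var.mean + var.amplitude * np.cos(
            2 * np.pi * (doy - var.peak_doy) / DAYS_PER_YEAR
        )
        anom = np.zeros(n)
        if var.sigma > 0:
            innov = rng.normal(0.0, var.sigma, size=n)
            anom[0] = innov[0] / math.sqrt(1.0 - var.rho**2)  # stationary start
            for i in range(1, n):
                anom[i] = var.rho * anom[i - 1] + innov[i]
        values = seasonal + var.trend_per_year * years_mid + anom
        if var.lower is not None or var.upper is not None:
            values = np.clip(values, var.lower, var.upper)
        out[name] = values
    return out


# ---------------------------------------------------------------------------
# pollutant generation


@dataclass(frozen=True)
class WeatherResponse:
    """Multiplicative weather response exp(Σ coef·(x − center)/scale).

    ``terms`` is a tuple of (variable, coef, center, scale); the derived
    variable ``ws10`` = sqrt(u10² + v10²) is available. A negative
    boundary-layer-height coefficient mimics dilution; a positive
    temperature coefficient mimics, e.g., enhanced secondary formation.
    An empty ``terms`` gives a factor that is identically 1.
    """

    terms: tuple[tuple[str, float, float, float], ...] = ()

    def factor(self, met: pd.DataFrame) -> np.ndarray:
        log_f = np.zeros(len(met))
        for var, coef, center, scale in self.terms:
            if var == "ws10":
                x = np.hypot(met["u10"].to_numpy(), met["v10"].to_numpy())
            else:
                x = met[var].to_numpy(float)
            log_f += coef * (x - center) / scale
        return np.exp(log_f)


def default_response() -> WeatherResponse:
    return WeatherResponse(
        terms=(
            ("blh", -0.30, 500.0, 150.0),
            ("t", 0.12, 288.0, 8.0),
            ("ws10", -0.10, 2.2, 1.2),
        )
    )


#: Weekday multipliers Mon..Sun: weekday traffic/industry above weekend.
DEFAULT_WEEKDAY_FACTORS = (1.02, 1.03, 1.03, 1.03, 1.02, 0.95, 0.92)


@dataclass(frozen=True)
class SyntheticPollutantConfig:
    pollutant: str = "PM2.5"
    baseline: float = 50.0
    trend_per_year: float | dict[int, float] = -0.05
    weekday_factors: tuple[float, ...] = DEFAULT_WEEKDAY_FACTORS
    response: WeatherResponse = field(default_factory=default_response)
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if len(self.weekday_factors) != 7 or any(w <= 0 for w in self.weekday_factors):
            raise ValueError("need 7 positive weekday multipliers")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _year_fraction(dates: pd.DatetimeIndex) -> np.ndarray:
    """(doy − 1) / days-in-year for each date, in [0, 1)."""
    days_in_year = np.where(dates.is_leap_year, 366.0, 365.0)
    return (dates.dayofyear.to_numpy(float) - 1.0) / days_in_year


def trend_factor(dates: pd.DatetimeIndex,
                 trend_per_year: float | dict[int, float]) -> np.ndarray:
    """Geometric emission-trend factor, 1.0 at the first day's year start.

    A scalar rate r gives (1+r)**(elapsed years); a {year: rate} schedule
    compounds each calendar year at its own rate (piecewise-exponential).
    """
    years = dates.year.to_numpy()
    frac = _year_fraction(dates)
    y0 = int(years[0])
    if isinstance(trend_per_year, dict):
        schedule = trend_per_year

        def rate(y: int) -> float:
            if y in schedule:
                return schedule[y]
            past = [yy for yy in schedule if yy <= y]
            return schedule[max(past)] if past else 0.0

        log_at_year_start = {y0: 0.0}
        for y in range(y0 + 1, int(years.max()) + 1):
            log_at_year_start[y] = log_at_year_start[y - 1] + math.log1p(rate(y - 1))
        log_f = np.array([log_at_year_start[int(y)] for y in years])
        log_f += frac * np.array([math.log1p(rate(int(y))) for y in years])
    else:
        log_f = (years - y0 + frac) * math.log1p(trend_per_year)
    return np.exp(log_f)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated pollutant series.

    ``frame`` has columns ``emission`` (baseline × trend × weekday, the
    noise-free emission-only series), ``weather_factor``, ``noise`` and
    ``observed``; the product of the first three reproduces ``observed``
    exactly, day by day.
    """

    frame: pd.DataFrame
    trend_per_year: float | dict[int, float]

    def emission_annual_means(self) -> pd.Series:
        em = self.frame["emission"]
        return em.groupby(em.index.year).mean()

    def emission_slope(self) -> float:
        """OLS slope (concentration units per year) of the noise-free
        emission-only annual means — the recovery target for deweathering."""
        means = self.emission_annual_means()
        years = means.index.to_numpy(float)
        return float(np.polyfit(years, means.to_numpy(), 1)[0])

    def realized_rate(self) -> float:
        """Annual fractional rate implied by the log-linear fit of the
        emission-only annual means (recovers a scalar configured trend)."""
        means = self.emission_annual_means()
        years = means.index.to_numpy(float)
        slope = np.polyfit(years, np.log(means.to_numpy()), 1)[0]
        return float(np.expm1(slope))


def generate_pollutant(met: pd.DataFrame, config: SyntheticPollutantConfig
                       ) -> tuple[PollutantSeries, SyntheticTruth]:
    """Generate a daily pollutant series over the met table's dates."""
    dates = met.index
    if not isinstance(dates, pd.DatetimeIndex) or len(dates) == 0:
        raise ValueError("met table must be date-indexed and non-empty")
    tf = trend_factor(dates, config.trend_per_year)
    wd = np.asarray(config.weekday_factors)[dates.dayofweek.to_numpy()]
    emission = config.baseline * tf * wd
    wf = config.response.factor(met)
    rng = np.random.default_rng(config.seed)
    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=len(dates))) \
        if config.noise_sigma > 0 else np.ones(len(dates))
    observed = emission * wf * noise
    truth = SyntheticTruth(
        frame=pd.DataFrame(
            {"emission": emission, "weather_factor": wf,
             "noise": noise, "observed": observed},
            index=dates,
        ),
        trend_per_year=config.trend_per_year,
    )
    series = PollutantSeries(config.pollutant,
                             pd.Series(observed, index=dates, name=config.pollutant),
                             basis="daily")
    return series, truth


def expand_hourly(series: PollutantSeries, diurnal_amplitude: float = 0.15,
                  peak_hour: int = 8) -> PollutantSeries:
    """Expand a daily series to 24 hourly values with a diurnal cycle whose
    daily arithmetic mean equals the daily value exactly (the sine pattern
    over 24 equally spaced hours sums to zero). Exists only to exercise the
    hourly reader and daily averaging."""
    if series.basis != "daily":
        raise ValueError("expand_hourly requires a daily series")
    hours = np.arange(24)
    pattern = 1.0 + diurnal_amplitude * np.sin(2 * np.pi * (hours - peak_hour) / 24.0)
    idx = (series.data.index.repeat(24)
           + pd.to_timedelta(np.tile(hours, len(series.data)), unit="h"))
    values = np.repeat(series.data.to_numpy(), 24) * np.tile(pattern, len(series.data))
    return PollutantSeries(series.pollutant, pd.Series(values, index=idx), basis="hourly")


# ---------------------------------------------------------------------------
# the default confounded scenario


@dataclass
class Scenario:
    """A complete synthetic study: long met history, an analysis-window
    pollutant series with truth, the resampling pool, and the feature table."""

    met: pd.DataFrame
    climatology: Climatology
    series: PollutantSeries
    truth: SyntheticTruth
    features: pd.DataFrame
    analysis_years: tuple[int, int]


def default_scenario(seed: int = 1,
                     start: str = "2015-01-01", end: str = "2022-12-31",
                     clim_start: str = "2001-01-01",
                     trend_per_year: float | dict[int, float] = -0.05,
                     blh_drift: float = 25.0,
                     noise_sigma: float = 0.25) -> Scenario:
    """Eight years of daily data with active weather confounding.

    The emission trend is −5% a⁻¹; the boundary layer deepens by
    ``blh_drift`` m a⁻¹ over the whole 2001–2022 history, so improving
    dilution adds a spurious downward component to the raw observed trend.
    The default drift is deliberately strong — it makes the weather-driven
    share of the raw slope comparable to the emission share (roughly a
    one-third bias), which is the regime the normalization exists for.
    The analysis window is a slice of the same history, and the full history
    is the resampling climatology.
    """
    variables = default_met_variables()
    variables["blh"] = replace(variables["blh"], trend_per_year=blh_drift)
    met_cfg = SyntheticMetConfig(clim_start, end, variables=variables, seed=seed)
    met = generate_met(met_cfg)

    poll_cfg = SyntheticPollutantConfig(
        trend_per_year=trend_per_year, noise_sigma=noise_sigma,
        seed=seed + 1_000_003,
    )
    analysis_met = met.loc[start:end]
    series, truth = generate_pollutant(analysis_met, poll_cfg)
    features = build_features(met, analysis_met.index, target=series.data)
    return Scenario(
        met=met,
        climatology=Climatology.from_met(met),
        series=series,
        truth=truth,
        features=features,
        analysis_years=(pd.Timestamp(start).year, pd.Timestamp(end).year),
    )
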