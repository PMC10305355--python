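"""Cause-specific premature mortality attributable to PM2.5 and O3.

For each cause the attributable deaths in a year are

    M = Y0 × Pop × (RR − 1)/RR

where Y0 is the cause-specific baseline mortality rate (deaths per person
per year), Pop the exposed population, RR the log-linear relative risk at
the annual exposure (``exp(β(C − C0))`` above the threshold, 1 at or below
it) and (RR − 1)/RR the attribution fraction, which is always in [0, 1): M
saturates below Y0 × Pop however large the exposure, and is identically zero
at or below the threshold.

Causes are fixed to their pollutant: stroke, ischemic heart disease (IHD),
chronic obstructive pulmonary disease (COPD) and lung cancer (LC) for PM2.5;
respiratory disease for O3. Deaths are computed in continuous units and only
rounded at presentation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
import yaml

from .health_risk import relative_risk
from .impact import fit_trend


@dataclass(frozen=True)
class CauseParams:
    """Exposure–response and baseline mortality for one cause of death."""

    cause: str
    pollutant: str
    beta: float
    c0: float
    y0: float  # baseline mortality rate, deaths per person per year

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.c0 < 0 or self.y0 < 0:
            raise ValueError(f"invalid parameters for cause {self.cause!r}")


@dataclass(frozen=True)
class MortalityParams:
    causes: tuple[CauseParams, ...]
    population: float

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be > 0")
        if not self.causes:
            raise ValueError("need at least one cause")

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.pollutant for c in self.causes))

    @classmethod
    def from_dict(cls, blob: dict) -> "MortalityParams":
        causes = []
        for name, cfg in blob["causes"].items():
            try:
                causes.append(CauseParams(
                    cause=name, pollutant=cfg["pollutant"],
                    beta=float(cfg["beta"]), c0=float(cfg["c0"]),
                    y0=float(cfg["y0"])))
            except KeyError as exc:
                raise ValueError(f"cause {name!r}: missing mortality key {exc}") from exc
        return cls(causes=tuple(causes), population=float(blob["population"]))

    @classmethod
    def from_yaml(cls, path) -> "MortalityParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "MortalityParams":
        ref = importlib.resources.files("metnorm") / "data" / "mortality_params.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


@dataclass
class MortalityEstimate:
    """Attributable deaths for one year and one exposure basis."""

    year: int
    basis: str  # "observed" | "deweathered"
    deaths: dict[str, float]               # per cause, continuous units
    attribution_fraction: dict[str, float]
    by_pollutant: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.deaths.values()))


def attributable_mortality(annual_concentration: dict[str, float],
                           params: MortalityParams, year: int = 0,
                           basis: str = "observed") -> MortalityEstimate:
    """Deaths attributable to the annual exposures, per cause and in total.

    ``annual_concentration`` maps pollutant id to the year's exposure metric
    (annual mean of daily concentrations). Every cause whose pollutant
    appears in the mapping must have parameters; a pollutant missing from
    the mapping raises.
    """
    deaths: dict[str, float] = {}
    fractions: dict[str, float] = {}
    by_pollutant: dict[str, float] = {}
    for cp in params.causes:
        if cp.pollutant not in annual_concentration:
            raise ValueError(f"no annual concentration for {cp.pollutant} "
                             f"(needed by cause {cp.cause!r})")
        conc = float(annual_concentration[cp.pollutant])
        rr = relative_risk(conc, cp.beta, cp.c0)
        frac = (rr - 1.0) / rr
        m = cp.y0 * params.population * frac
        deaths[cp.cause] = m
        fractions[cp.cause] = frac
        by_pollutant[cp.pollutant] = by_pollutant.get(cp.pollutant, 0.0) + m
    return MortalityEstimate(year=year, basis=basis, deaths=deaths,
                             attribution_fraction=fractions,
                             by_pollutant=by_pollutant)


def mortality_series(annual_concentrations: pd.DataFrame,
                     params: MortalityParams,
                     basis: str = "observed") -> pd.DataFrame:
    """Tidy per-year mortality: columns year, basis, cause, deaths, with a
    ``total`` row per year. ``annual_concentrations`` is year-indexed, one
    column per pollutant."""
    rows = []
    for year, conc_row in annual_concentrations.iterrows():
        est = attributable_mortality(conc_row.dropna().to_dict(), params,
                                     year=int(year), basis=basis)
        for cause, m in est.deaths.items():
            rows.append({"year": int(year), "basis": basis,
                         "cause": cause, "deaths": m})
        rows.append({"year": int(year), "basis": basis,
                     "cause": "total", "deaths": est.total})
    return pd.DataFrame(rows)


def yearly_totals(tidy: pd.DataFrame, cause: str = "total") -> pd.Series:
    """Extract a year-indexed series of deaths for one cause (or the total)."""
    sub = tidy[tidy["cause"] == cause]
    out = pd.Series(sub["deaths"].to_numpy(), index=sub["year"].to_numpy())
    out.index.name = "year"
    return out.sort_index()


def mortality_trend(yearly_deaths: pd.Series) -> tuple[float, float]:
    """OLS slope of yearly deaths on year (deaths per year of change), with
    its standard error. Requires at least three years."""
    est = fit_trend(yearly_deaths)
    return est.slope, est.stderr


def avoided_deaths(yearly_deaths: pd.Series, base_year: int, end_year: int) -> float:
    """Difference total(base) − total(end): positive when deaths declined.
    Antisymmetric in the two years."""
    for y in (base_year, end_year):
        if y not in yearly_deaths.index:
            raise ValueError(f"year {y} missing from mortality series")
    return float(yearly_deaths.loc[base_year] - yearly_deaths.loc[end_year])
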