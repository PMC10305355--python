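"""Health-risk-based air quality index (HAQI).

The conventional AQI maps each pollutant's concentration through a
breakpoint ladder and takes the maximum, which ignores the joint burden of
simultaneous exposure. The HAQI instead works on the risk scale:

1. per-pollutant relative risk   RR_i = exp(β_i (C_i − C0_i)) for C_i > C0_i,
   else 1;
2. total excess risk             ER = Σ_i (RR_i − 1),  combined risk RR′ = ER + 1;
3. equivalent concentration      C′_i = ln(RR′)/β_i + C0_i — the single-pollutant
   concentration whose risk equals the combined risk;
4. each C′_i is mapped through the pollutant's AQI breakpoint ladder
   (piecewise-linear), and the overall HAQI is the maximum, with its argmax
   the dominant pollutant.

Because RR′ ≥ RR_i, every equivalent concentration is at least the actual
one, so the HAQI dominates the conventional AQI pollutant by pollutant.

β, C0 and the ladders are configuration, not code; the shipped defaults
(see ``metnorm/data/haqi_params.yaml``) use the Chinese AQI standard's
breakpoint tables and representative exposure–response coefficients, and can
be swapped wholesale.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ingest import POLLUTANT_ORDER


def relative_risk(concentration, beta: float, c0: float):
    """RR = exp(β(C − C0)) above the no-effect threshold C0, exactly 1 at or
    below it. Vectorized over ``concentration``."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    c = np.asarray(concentration, float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    rr = np.where(c > c0, np.exp(beta * (c - c0)), 1.0)
    return float(rr) if rr.ndim == 0 else rr


def combined_risk(rrs) -> tuple[float, float]:
    """Total excess risk and combined relative risk for simultaneous
    exposure: ER = Σ(RR_i − 1), RR′ = ER + 1."""
    arr = np.asarray(list(rrs), float)
    if arr.size == 0:
        raise ValueError("need at least one relative risk")
    if np.any(arr < 1):
        raise ValueError("relative risks must be >= 1")
    er_total = float(np.sum(arr - 1.0))
    return er_total, er_total + 1.0


def equivalent_concentration(rr_prime: float, beta: float, c0: float) -> float:
    """C′ = ln(RR′)/β + C0 — inverse of :func:`relative_risk` at RR′."""
    if rr_prime < 1:
        raise ValueError("combined risk must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return math.log(rr_prime) / beta + c0


@dataclass(frozen=True)
class ExposureResponse:
    """Log-linear exposure–response: coefficient β (per unit concentration)
    and no-effect threshold C0 (pollutant units)."""

    beta: float
    c0: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.c0 < 0:
            raise ValueError("C0 must be >= 0")


@dataclass(frozen=True)
class BreakpointLadder:
    """Ordered (concentration, AQI) breakpoints for one pollutant.

    ``concentrations[j]`` is the upper concentration limit of health
    category j+1 and maps to ``aqi[j]``. Both sequences must be strictly
    increasing and positive.
    """

    concentrations: tuple[float, ...]
    aqi: tuple[float, ...]

    def __post_init__(self) -> None:
        c, a = np.asarray(self.concentrations), np.asarray(self.aqi)
        if len(c) != len(a) or len(c) < 2:
            raise ValueError("ladder needs >= 2 matched breakpoints")
        if np.any(np.diff(c) <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if c[0] <= 0 or a[0] <= 0:
            raise ValueError("first breakpoint must be positive")


def haqi_pollutant(c_equiv: float, ladder: BreakpointLadder,
                   above_scale: str = "extrapolate") -> float:
    """Map an equivalent concentration through a breakpoint ladder.

    Within the first category the rule is proportional
    (AQI_1 × C′/C_1); within later categories it is piecewise-linear between
    the bracketing breakpoints; above the top breakpoint the last segment's
    slope is extrapolated (or the top AQI returned, with
    ``above_scale="cap"``).
    """
    if c_equiv < 0:
        raise ValueError("equivalent concentration must be >= 0")
    c = np.asarray(ladder.concentrations, float)
    a = np.asarray(ladder.aqi, float)
    if c_equiv <= c[0]:
        return float(a[0] * c_equiv / c[0])
    if c_equiv > c[-1]:
        if above_scale == "cap":
            return float(a[-1])
        slope = (a[-1] - a[-2]) / (c[-1] - c[-2])
        return float(a[-1] + slope * (c_equiv - c[-1]))
    j = int(np.searchsorted(c, c_equiv, side="left"))
    slope = (a[j] - a[j - 1]) / (c[j] - c[j - 1])
    return float(a[j - 1] + slope * (c_equiv - c[j - 1]))


def haqi_overall(per_pollutant: dict[str, float]) -> tuple[float, str]:
    """Maximum per-pollutant index and the dominant pollutant; exact ties
    are broken by the fixed order PM2.5, PM10, O3, NO2, SO2, CO."""
    if not per_pollutant:
        raise ValueError("no per-pollutant indexes")
    order = {p: i for i, p in enumerate(POLLUTANT_ORDER)}
    best = max(per_pollutant,
               key=lambda p: (per_pollutant[p], -order.get(p, len(order))))
    return per_pollutant[best], best


@dataclass(frozen=True)
class HealthRiskParams:
    """β/C0 and breakpoint ladders for every pollutant in play."""

    exposure: dict[str, ExposureResponse]
    ladders: dict[str, BreakpointLadder]

    def __post_init__(self) -> None:
        missing = set(self.exposure) - set(self.ladders)
        if missing:
            raise ValueError(f"pollutants lacking a ladder: {sorted(missing)}")

    @classmethod
    def from_dict(cls, blob: dict) -> "HealthRiskParams":
        exposure = {}
        ladders = {}
        for pollutant, cfg in blob["pollutants"].items():
            try:
                exposure[pollutant] = ExposureResponse(float(cfg["beta"]),
                                                       float(cfg["c0"]))
                ladders[pollutant] = BreakpointLadder(
                    tuple(float(x) for x in cfg["breakpoints"]),
                    tuple(float(x) for x in cfg["aqi"]),
                )
            except KeyError as exc:
                raise ValueError(f"{pollutant}: missing health-risk key {exc}") from exc
        return cls(exposure=exposure, ladders=ladders)

    @classmethod
    def from_yaml(cls, path) -> "HealthRiskParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "HealthRiskParams":
        ref = importlib.resources.files("metnorm") / "data" / "haqi_params.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def compute_haqi(concentrations: pd.DataFrame, params: HealthRiskParams,
                 above_scale: str = "extrapolate"
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily HAQI for a wide table of concentrations (one column per
    pollutant, date index), in each pollutant's native units.

    Returns ``(components, overall)``: the components table is tidy
    (date, pollutant, rr, c_equiv, haqi_i); the overall table has the
    maximum index and the dominant pollutant per day.
    """
    pollutants = [p for p in concentrations.columns if p in params.exposure]
    if not pollutants:
        raise ValueError("no configured pollutants in the concentration table")
    rr = {
        p: relative_risk(concentrations[p].to_numpy(float),
                         params.exposure[p].beta, params.exposure[p].c0)
        for p in pollutants
    }
    rr_mat = np.column_stack([rr[p] for p in pollutants])
    er_total = np.sum(rr_mat - 1.0, axis=1)
    rr_prime = er_total + 1.0

    comp_rows = []
    haqi_cols = {}
    for p in pollutants:
        ex = params.exposure[p]
        c_eq = np.log(rr_prime) / ex.beta + ex.c0
        haqi_i = np.array([haqi_pollutant(c, params.ladders[p], above_scale)
                           for c in c_eq])
        haqi_cols[p] = haqi_i
        comp_rows.append(pd.DataFrame(
            {"date": concentrations.index, "pollutant": p,
             "rr": rr[p], "c_equiv": c_eq, "haqi_i": haqi_i}))
    components = pd.concat(comp_rows, ignore_index=True)

    haqi_frame = pd.DataFrame(haqi_cols, index=concentrations.index)
    ordered = [p for p in POLLUTANT_ORDER if p in haqi_frame.columns]
    haqi_frame = haqi_frame[ordered]
    overall = pd.DataFrame(
        {
            "haqi": haqi_frame.max(axis=1),
            "dominant": haqi_frame.idxmax(axis=1),  # first max in fixed order
        },
        index=concentrations.index,
    )
    return components, overall


def haqi_drivers(observed_haqi: pd.Series, deweathered_haqi: pd.Series,
                 base_year: int, end_year: int) -> dict[str, float]:
    """Decompose the change in annual-mean HAQI between two years into an
    emission-driven share (the deweathered change) and a meteorology-driven
    share (the remainder); shares sum to 100 by construction."""
    def year_mean(series: pd.Series, year: int) -> float:
        vals = series[series.index.year == year].dropna()
        if vals.empty:
            raise ValueError(f"no HAQI values in {year}")
        return float(vals.mean())

    delta_obs = year_mean(observed_haqi, end_year) - year_mean(observed_haqi, base_year)
    delta_dew = year_mean(deweathered_haqi, end_year) - year_mean(deweathered_haqi, base_year)
    if delta_obs == 0:
        raise ValueError("observed HAQI change is zero; shares undefined")
    emission_share = 100.0 * delta_dew / delta_obs
    return {
        "delta_observed": delta_obs,
        "delta_deweathered": delta_dew,
        "emission_share_pct": emission_share,
        "met_share_pct": 100.0 - emission_share,
    }


def relative_decline(start_value: float, end_value: float) -> float:
    """Percent decline from start to end: 100 × (start − end)/start."""
    if start_value <= 0:
        raise ValueError("start value must be > 0")
    return 100.0 * (start_value - end_value) / start_value
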