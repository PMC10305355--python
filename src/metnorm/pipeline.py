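"""End-to-end orchestration: ingest → train → deweather → trends → HAQI →
mortality, with a machine-readable run manifest and summary figures.

Every stage's outputs are tidy CSVs under the run's output directory, and
every parameter and seed that produced them is serialized into
``manifest.json``, so any number in any output is regenerable from the
manifest alone. A failure in any stage aborts the run with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deweather import MeteoNormalizer, save_model
from .health_risk import HealthRiskParams, compute_haqi, haqi_drivers
from .impact import annual_means, met_impact_by_month, trend_table
from .ingest import (
    Climatology,
    PollutantSeries,
    build_features,
    daily_average,
    read_met_csv,
    read_pollutant_csv,
    write_met_csv,
    write_pollutant_csv,
)
from .mortality import MortalityParams, mortality_series, yearly_totals, avoided_deaths
from .synthetic import (
    SyntheticMetConfig,
    SyntheticPollutantConfig,
    WeatherResponse,
    default_met_variables,
    generate_met,
    generate_pollutant,
)
from dataclasses import replace


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ModelSpec:
    n_estimators: int = 300
    min_samples_leaf: int = 5
    train_fraction: float = 0.70
    cv_folds: int = 5


@dataclass(frozen=True)
class SyntheticSpec:
    """Per-pollutant synthetic generator settings used when no input CSVs
    are given. ``response`` is a list of [variable, coef, center, scale]."""

    baseline: float = 50.0
    trend_per_year: float = -0.05
    noise_sigma: float = 0.25
    response: tuple = (("blh", -0.30, 500.0, 150.0),
                       ("t", 0.12, 288.0, 8.0),
                       ("ws10", -0.10, 2.2, 1.2))
    blh_drift: float = 25.0


DEFAULT_SYNTHETIC = {
    "PM2.5": SyntheticSpec(),
    "O3": SyntheticSpec(baseline=80.0, trend_per_year=0.02, noise_sigma=0.20,
                        response=(("t", 0.20, 288.0, 8.0),
                                  ("sr", 0.12, 1.5e7, 8.0e6),
                                  ("rh", -0.06, 70.0, 10.0))),
}


@dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into the manifest."""

    output_dir: str
    pollutants: tuple[str, ...] = ("PM2.5", "O3")
    analysis_start: str = "2015-01-01"
    analysis_end: str = "2022-12-31"
    climatology_start: str = "2001-01-01"
    pollutant_csv: str | None = None   # None → synthetic inputs
    met_csv: str | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    n_resamples: int = 1000
    seed: int = 1
    haqi_params: str | None = None      # None → packaged defaults
    mortality_params: str | None = None
    synthetic: dict[str, SyntheticSpec] = field(
        default_factory=lambda: dict(DEFAULT_SYNTHETIC))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh)
        if "model" in blob:
            blob["model"] = ModelSpec(**blob["model"])
        if "synthetic" in blob:
            blob["synthetic"] = {
                p: SyntheticSpec(**{**spec,
                                    "response": tuple(tuple(t) for t in
                                                      spec.get("response",
                                                               SyntheticSpec().response))})
                for p, spec in blob["synthetic"].items()
            }
        if "pollutants" in blob:
            blob["pollutants"] = tuple(blob["pollutants"])
        return cls(**blob)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _load_inputs(cfg: RunConfig, outdir: Path):
    """Read or synthesize the met history and the daily pollutant series."""
    if cfg.met_csv is not None:
        met = read_met_csv(cfg.met_csv)
    else:
        variables = default_met_variables()
        drift = max((spec.blh_drift for spec in cfg.synthetic.values()), default=0.0)
        variables["blh"] = replace(variables["blh"], trend_per_year=drift)
        met = generate_met(SyntheticMetConfig(cfg.climatology_start, cfg.analysis_end,
                                              variables=variables, seed=cfg.seed))
        write_met_csv(met, outdir / "inputs" / "met.csv")

    analysis_met = met.loc[cfg.analysis_start:cfg.analysis_end]
    series: dict[str, PollutantSeries] = {}
    truths = {}
    for k, pollutant in enumerate(cfg.pollutants):
        if cfg.pollutant_csv is not None:
            s = read_pollutant_csv(cfg.pollutant_csv, pollutant)
            if s.basis == "hourly":
                s = daily_average(s)
            s = PollutantSeries(pollutant,
                                s.data.loc[cfg.analysis_start:cfg.analysis_end],
                                basis="daily")
        else:
            spec = cfg.synthetic.get(pollutant, SyntheticSpec())
            pc = SyntheticPollutantConfig(
                pollutant=pollutant, baseline=spec.baseline,
                trend_per_year=spec.trend_per_year,
                response=WeatherResponse(tuple(tuple(t) for t in spec.response)),
                noise_sigma=spec.noise_sigma,
                seed=cfg.seed + 1_000_003 * (k + 1),
            )
            s, truth = generate_pollutant(analysis_met, pc)
            truths[pollutant] = truth
            write_pollutant_csv(s, outdir / "inputs" / f"pollutant_{pollutant}.csv")
            truth.frame.to_csv(outdir / "inputs" / f"truth_{pollutant}.csv",
                               float_format="%.8g")
        series[pollutant] = s
    return met, analysis_met, series, truths


def run_pipeline(cfg: RunConfig, make_plots: bool = True) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    outdir = Path(cfg.output_dir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "metnorm",
        "version": __version__,
        "config": _jsonable(cfg),
        "outputs": {},
        "metrics": {},
    }

    try:
        met, analysis_met, series, truths = _load_inputs(cfg, outdir)
        climatology = Climatology.from_met(met)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    models: dict[str, MeteoNormalizer] = {}
    dew: dict[str, pd.Series] = {}
    fit_rows = []
    importance_rows = []
    try:
        for pollutant, s in series.items():
            feats = build_features(met, s.data.index, target=s.data)
            model = MeteoNormalizer(
                n_estimators=cfg.model.n_estimators,
                min_samples_leaf=cfg.model.min_samples_leaf,
                train_fraction=cfg.model.train_fraction,
                cv_folds=cfg.model.cv_folds,
                random_state=cfg.seed,
            ).fit(feats)
            models[pollutant] = model
            rep = model.fit_report_
            fit_rows.append({"pollutant": pollutant, "r": rep.r,
                             "nmse": rep.nmse, "rmse": rep.rmse})
            for feat, imp in rep.importances.items():
                importance_rows.append({"pollutant": pollutant,
                                        "feature": feat, "importance": imp})
            save_model(model, outdir / f"model_{pollutant}.joblib")
    except Exception as exc:
        raise PipelineError("train", exc) from exc
    pd.DataFrame(fit_rows).to_csv(outdir / "cv_metrics.csv", index=False)
    pd.DataFrame(importance_rows).to_csv(outdir / "feature_importance.csv", index=False)
    manifest["outputs"]["cv_metrics"] = "cv_metrics.csv"
    manifest["metrics"]["cv"] = fit_rows

    try:
        for k, (pollutant, s) in enumerate(series.items()):
            feats = build_features(met, s.data.index, target=s.data)
            result = models[pollutant].deweather(
                feats, climatology, n_resamples=cfg.n_resamples,
                random_state=cfg.seed + 7_919 * (k + 1))
            result.frame.to_csv(outdir / f"deweathered_{pollutant}.csv",
                                index_label="date", float_format="%.8g")
            dew[pollutant] = result.frame["deweathered"]
    except Exception as exc:
        raise PipelineError("deweather", exc) from exc
    manifest["outputs"]["deweathered"] = [f"deweathered_{p}.csv" for p in series]

    try:
        y0 = pd.Timestamp(cfg.analysis_start).year
        y1 = pd.Timestamp(cfg.analysis_end).year
        n_years = y1 - y0 + 1
        if n_years >= 8:
            periods = ((y0, y1), (y0, y0 + n_years // 2 - 1), (y0 + n_years // 2, y1))
        else:
            periods = ((y0, y1),)
        trends = pd.concat(
            [trend_table(series[p].data, dew[p], pollutant=p, periods=periods)
             for p in series], ignore_index=True)
        trends.to_csv(outdir / "trends.csv", index=False)
        impact = pd.concat(
            {p: met_impact_by_month(series[p].data, dew[p]) for p in series},
            names=["pollutant"]).reset_index()
        impact.to_csv(outdir / "met_impact_monthly.csv", index=False)
    except Exception as exc:
        raise PipelineError("impact_trends", exc) from exc
    manifest["outputs"]["trends"] = "trends.csv"
    manifest["outputs"]["met_impact"] = "met_impact_monthly.csv"
    manifest["metrics"]["trends"] = _jsonable(trends.to_dict(orient="records"))

    try:
        haqi_params = (HealthRiskParams.from_yaml(cfg.haqi_params)
                       if cfg.haqi_params else HealthRiskParams.default())
        conc_obs = pd.DataFrame({p: series[p].data for p in series})
        conc_dew = pd.DataFrame(dew)
        comp_obs, overall_obs = compute_haqi(conc_obs, haqi_params)
        comp_dew, overall_dew = compute_haqi(conc_dew, haqi_params)
        comp_obs.to_csv(outdir / "haqi_components_observed.csv", index=False,
                        float_format="%.6g")
        overall_obs.to_csv(outdir / "haqi_observed.csv", index_label="date",
                           float_format="%.6g")
        overall_dew.to_csv(outdir / "haqi_deweathered.csv", index_label="date",
                           float_format="%.6g")
        drivers = haqi_drivers(overall_obs["haqi"], overall_dew["haqi"], y0, y1)
        manifest["metrics"]["haqi_drivers"] = _jsonable(drivers)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("health_risk", exc) from exc
    manifest["outputs"]["haqi"] = ["haqi_observed.csv", "haqi_deweathered.csv",
                                   "haqi_components_observed.csv"]

    try:
        mort_params = (MortalityParams.from_yaml(cfg.mortality_params)
                       if cfg.mortality_params else MortalityParams.default())
        needed = [p for p in mort_params.pollutants if p in conc_obs.columns]
        restricted = MortalityParams(
            causes=tuple(c for c in mort_params.causes if c.pollutant in needed),
            population=mort_params.population)
        ann_obs = pd.DataFrame({p: annual_means(conc_obs[p]) for p in needed})
        ann_dew = pd.DataFrame({p: annual_means(conc_dew[p]) for p in needed})
        tidy = pd.concat([mortality_series(ann_obs, restricted, basis="observed"),
                          mortality_series(ann_dew, restricted, basis="deweathered")],
                         ignore_index=True)
        tidy.to_csv(outdir / "mortality.csv", index=False, float_format="%.6g")
        totals_dew = yearly_totals(tidy[tidy["basis"] == "deweathered"])
        manifest["metrics"]["avoided_deaths_deweathered"] = avoided_deaths(
            totals_dew, y0, y1)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mortality", exc) from exc
    manifest["outputs"]["mortality"] = "mortality.csv"

    if make_plots:
        try:
            _plots(outdir, series, dew, impact, overall_obs, overall_dew, tidy)
            manifest["outputs"]["figures"] = [
                "fig_annual_means.png", "fig_met_impact.png",
                "fig_haqi.png", "fig_mortality.png"]
        except Exception as exc:
            raise PipelineError("report", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plots(outdir, series, dew, impact, overall_obs, overall_dew, tidy_mortality):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(series), figsize=(5 * len(series), 3.5),
                             squeeze=False)
    for ax, (p, s) in zip(axes[0], series.items()):
        annual_means(s.data).plot(ax=ax, marker="o", label="observed")
        annual_means(dew[p]).plot(ax=ax, marker="s", label="deweathered")
        ax.set_title(p)
        ax.set_ylabel("concentration")
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_annual_means.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for p, grp in impact.groupby("pollutant"):
        ax.errorbar(grp["month"], grp["met_impact_index"], yerr=grp["sd"],
                    marker="o", capsize=3, label=p)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("month")
    ax.set_ylabel("MET impact index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_met_impact.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    annual_means(overall_obs["haqi"]).plot(kind="bar", ax=ax, alpha=0.7,
                                           label="observed", position=0, width=0.4)
    annual_means(overall_dew["haqi"]).plot(kind="bar", ax=ax, alpha=0.7,
                                           color="C1", label="deweathered",
                                           position=1, width=0.4)
    ax.set_ylabel("annual mean HAQI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_haqi.png", dpi=120)
    plt.close(fig)

    obs = tidy_mortality[(tidy_mortality["basis"] == "observed")
                         & (tidy_mortality["cause"] != "total")]
    pivot = obs.pivot(index="year", columns="cause", values="deaths")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    pivot.plot(kind="bar", stacked=True, ax=ax)
    ax.set_ylabel("attributable deaths")
    fig.tight_layout()
    fig.savefig(outdir / "fig_mortality.png", dpi=120)
    plt.close(fig)
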