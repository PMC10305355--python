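"""MET impact index, annual trends, emission contributions, COVID sensitivity."""

import numpy as np
import pandas as pd
import pytest

from metnorm import (
    annual_means,
    covid_adjust,
    emission_contribution,
    fit_trend,
    met_impact_by_month,
    met_impact_by_season,
    met_impact_index,
    met_impact_period,
    trend_table,
)
from metnorm.impact import COLD_MONTHS, WARM_MONTHS, monthly_means


def daily(values_by_year: dict[int, float]) -> pd.Series:
    parts = []
    for year, value in values_by_year.items():
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        parts.append(pd.Series(value, index=idx))
    return pd.concat(parts)


class TestMetImpactIndex:
    def test_equal_means_give_zero(self):
        assert met_impact_index(50.0, 50.0) == 0.0

    def test_adverse_meteorology_positive(self):
        assert met_impact_index(50.0, 40.0) == pytest.approx(0.2)

    def test_favorable_meteorology_negative(self):
        assert met_impact_index(40.0, 50.0) == pytest.approx(-0.25)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            met_impact_index(0.0, 10.0)

    def test_index_below_one_for_positive_concentrations(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(1, 100, 50)
        dew = rng.uniform(1, 100, 50)
        assert (met_impact_index(obs, dew) < 1).all()


class TestAnnualMeans:
    def test_constant_year(self):
        assert annual_means(daily({2015: 10.0})).loc[2015] == 10.0

    def test_two_years(self):
        means = annual_means(daily({2015: 10.0, 2016: 20.0}))
        assert means.tolist() == [10.0, 20.0]

    def test_noise_free_trend_matches_truth(self):
        from metnorm import default_scenario
        sc = default_scenario(seed=2, start="2015-01-01", end="2017-12-31",
                              clim_start="2014-01-01")
        em = sc.truth.frame["emission"]
        pd.testing.assert_series_equal(annual_means(em),
                                       sc.truth.emission_annual_means(),
                                       check_names=False)


class TestFitTrend:
    def test_collinear_points_exact(self):
        means = pd.Series([10.0, 8.0, 6.0, 4.0], index=range(2015, 2019))
        est = fit_trend(means)
        assert est.slope == pytest.approx(-2.0)
        assert est.stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_means_zero_slope(self):
        means = pd.Series([5.0] * 4, index=range(2015, 2019))
        assert fit_trend(means).slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        years = np.arange(2015, 2023, dtype=float)
        vals = rng.uniform(10, 60, len(years))
        est = fit_trend(pd.Series(vals, index=years.astype(int)))
        # brute-force normal equations on centered years (well-conditioned)
        X = np.column_stack([np.ones_like(years), years - years.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        assert est.slope == pytest.approx(beta[1], abs=1e-10)

    def test_period_selection_and_min_years(self):
        means = pd.Series(np.arange(8.0), index=range(2015, 2023))
        est = fit_trend(means, period=(2019, 2022))
        assert (est.start_year, est.end_year, est.n_years) == (2019, 2022, 4)
        with pytest.raises(ValueError):
            fit_trend(means, period=(2015, 2016))


class TestEmissionContribution:
    @pytest.mark.parametrize(
        "dew,obs,expected",
        [(-1.89, -3.12, 61), (-3.27, -5.27, 62), (-0.64, -1.15, 56),
         (-1.94, -2.75, 71), (-0.03, -0.04, 75)],
    )
    def test_reported_slope_pairs(self, dew, obs, expected):
        assert emission_contribution(dew, obs) == expected

    def test_identity_is_100(self):
        assert emission_contribution(-2.5, -2.5) == 100
        assert emission_contribution(0.7, 0.7) == 100

    def test_opposite_signs_undefined(self):
        assert emission_contribution(1.0, -1.0) is None

    def test_zero_observed_rejected(self):
        with pytest.raises(ZeroDivisionError):
            emission_contribution(-1.0, 0.0)


class TestCovidAdjust:
    @pytest.fixture
    def series(self):
        rng = np.random.default_rng(5)
        idx = pd.date_range("2019-01-01", "2021-12-31", freq="D")
        return pd.Series(rng.uniform(10, 80, len(idx)), index=idx)

    def test_2020_matches_2019_means(self, series):
        # equal up to the leap day: 2020 counts Feb 28's value twice
        adj = covid_adjust(series)
        means = annual_means(adj)
        assert means.loc[2020] == pytest.approx(means.loc[2019], rel=5e-3)
        # dropping the duplicated leap day restores exact equality
        non_leap = adj[~((adj.index.month == 2) & (adj.index.day == 29))]
        assert annual_means(non_leap).loc[2020] == pytest.approx(
            means.loc[2019], rel=1e-12)

    def test_other_years_untouched(self, series):
        adj = covid_adjust(series)
        for year in (2019, 2021):
            np.testing.assert_array_equal(
                adj[adj.index.year == year].to_numpy(),
                series[series.index.year == year].to_numpy())

    def test_leap_day_takes_feb_28(self, series):
        adj = covid_adjust(series)
        assert adj.loc["2020-02-29"] == series.loc["2019-02-28"]
        assert adj.loc["2020-02-28"] == series.loc["2019-02-28"]

    def test_missing_2019_rejected(self):
        idx = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        with pytest.raises(ValueError):
            covid_adjust(pd.Series(1.0, index=idx))


class TestDecomposition:
    def test_slope_decomposition_identity(self):
        # OLS linearity: slope(obs) = slope(dew) + slope(obs - dew)
        rng = np.random.default_rng(11)
        idx = pd.date_range("2015-01-01", "2022-12-31", freq="D")
        obs = pd.Series(rng.uniform(20, 80, len(idx)), index=idx)
        dew = pd.Series(rng.uniform(20, 80, len(idx)), index=idx)
        s_obs = fit_trend(annual_means(obs)).slope
        s_dew = fit_trend(annual_means(dew)).slope
        s_met = fit_trend(annual_means(obs - dew)).slope
        assert s_obs == pytest.approx(s_dew + s_met, abs=1e-10)

    def test_seasons_partition_months(self):
        assert sorted(WARM_MONTHS + COLD_MONTHS) == list(range(1, 13))
        assert not set(WARM_MONTHS) & set(COLD_MONTHS)

    def test_period_index_is_not_mean_of_monthly_indexes(self):
        # guards against averaging monthly indexes: with unequal monthly
        # observed means the ratio-of-means differs from the mean-of-ratios
        idx = pd.date_range("2015-01-01", "2015-12-31", freq="D")
        obs = pd.Series(np.where(idx.month <= 6, 100.0, 20.0), index=idx)
        dew = pd.Series(np.where(idx.month <= 6, 50.0, 18.0), index=idx)
        period_idx, _ = met_impact_period(obs, dew, (2015, 2015))
        monthly = monthly_means(obs), monthly_means(dew)
        naive = met_impact_index(monthly[0].to_numpy(),
                                 monthly[1].to_numpy()).mean()
        assert period_idx != pytest.approx(naive, rel=1e-3)


def test_met_impact_by_month_and_season_shapes():
    rng = np.random.default_rng(3)
    idx = pd.date_range("2015-01-01", "2018-12-31", freq="D")
    obs = pd.Series(rng.uniform(30, 90, len(idx)), index=idx)
    dew = pd.Series(rng.uniform(30, 90, len(idx)), index=idx)
    monthly = met_impact_by_month(obs, dew)
    assert list(monthly.index) == list(range(1, 13))
    assert monthly["sd"].notna().all()  # 4 years -> sd defined
    seasonal = met_impact_by_season(obs, dew)
    assert set(seasonal.index) == {"warm", "cold"}


def test_trend_table_tidy_output():
    rng = np.random.default_rng(4)
    idx = pd.date_range("2015-01-01", "2022-12-31", freq="D")
    trend = 1.0 - 0.04 * (idx.year - 2015)
    obs = pd.Series(60.0 * trend * rng.lognormal(0, 0.1, len(idx)), index=idx)
    dew = pd.Series(55.0 * trend * rng.lognormal(0, 0.05, len(idx)), index=idx)
    table = trend_table(obs, dew, pollutant="PM2.5")
    assert list(table["period"]) == ["2015-2022", "2015-2018", "2019-2022"]
    assert table["contribution_pct"].notna().all()
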