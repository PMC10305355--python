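"""HAQI machinery: relative risk, risk combination, equivalent concentrations,
breakpoint interpolation, and the dominance/monotonicity invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metnorm import (
    BreakpointLadder,
    ExposureResponse,
    HealthRiskParams,
    combined_risk,
    compute_haqi,
    equivalent_concentration,
    haqi_drivers,
    haqi_overall,
    haqi_pollutant,
    relative_decline,
    relative_risk,
)

TOY_LADDER = BreakpointLadder((50.0, 150.0), (50.0, 100.0))

TOY_PARAMS = HealthRiskParams(
    exposure={
        "PM2.5": ExposureResponse(beta=0.0004, c0=10.0),
        "O3": ExposureResponse(beta=0.0005, c0=75.0),
        "SO2": ExposureResponse(beta=0.0008, c0=10.0),
    },
    ladders={
        "PM2.5": BreakpointLadder((35.0, 75.0, 115.0, 150.0),
                                  (50.0, 100.0, 150.0, 200.0)),
        "O3": BreakpointLadder((100.0, 160.0, 215.0), (50.0, 100.0, 150.0)),
        "SO2": BreakpointLadder((50.0, 150.0, 475.0), (50.0, 100.0, 150.0)),
    },
)


class TestRelativeRisk:
    def test_at_threshold_is_one(self):
        assert relative_risk(20.0, beta=0.001, c0=20.0) == 1.0
        assert relative_risk(5.0, beta=0.001, c0=20.0) == 1.0

    def test_closed_form_e(self):
        assert relative_risk(1010.0, beta=0.001, c0=10.0) == pytest.approx(math.e)

    def test_direct_evaluation(self):
        assert relative_risk(110.0, beta=0.0005, c0=10.0) == pytest.approx(
            math.exp(0.05))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0, beta=0.001, c0=0.0)
        with pytest.raises(ValueError):
            relative_risk(10.0, beta=0.0, c0=0.0)


class TestCombinedRisk:
    def test_all_unity(self):
        assert combined_risk([1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_excess_risks_add(self):
        er, rr = combined_risk([1.2, 1.3])
        assert er == pytest.approx(0.5)
        assert rr == pytest.approx(1.5)

    def test_single_pollutant_collapses(self):
        _, rr = combined_risk([1.37])
        assert rr == pytest.approx(1.37)

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            combined_risk([0.99, 1.2])


class TestEquivalentConcentration:
    def test_unit_risk_gives_threshold(self):
        assert equivalent_concentration(1.0, beta=0.002, c0=12.0) == 12.0

    def test_closed_form(self):
        assert equivalent_concentration(math.e, beta=0.001, c0=5.0) == pytest.approx(
            1005.0)

    def test_round_trip_inverse(self):
        for c in (30.0, 75.0, 180.0):
            rr = relative_risk(c, beta=0.0007, c0=10.0)
            assert equivalent_concentration(rr, beta=0.0007, c0=10.0) == pytest.approx(
                c, abs=1e-9)

    def test_risk_below_one_rejected(self):
        with pytest.raises(ValueError):
            equivalent_concentration(0.9, beta=0.001, c0=0.0)


class TestHaqiPollutant:
    def test_value_at_breakpoint_is_its_aqi(self):
        assert haqi_pollutant(150.0, TOY_LADDER) == 100.0
        assert haqi_pollutant(50.0, TOY_LADDER) == 50.0

    def test_segment_midpoint(self):
        assert haqi_pollutant(100.0, TOY_LADDER) == 75.0

    def test_first_category_proportional(self):
        assert haqi_pollutant(25.0, TOY_LADDER) == 25.0
        assert haqi_pollutant(0.0, TOY_LADDER) == 0.0

    def test_above_scale_extrapolates_last_segment(self):
        # last segment slope = 50/100 = 0.5
        assert haqi_pollutant(250.0, TOY_LADDER) == pytest.approx(150.0)
        assert haqi_pollutant(250.0, TOY_LADDER, above_scale="cap") == 100.0

    def test_malformed_ladder_rejected(self):
        with pytest.raises(ValueError):
            BreakpointLadder((50.0, 40.0), (50.0, 100.0))
        with pytest.raises(ValueError):
            BreakpointLadder((50.0,), (50.0,))


class TestHaqiOverall:
    def test_maximum_wins(self):
        value, dominant = haqi_overall({"PM2.5": 80.0, "PM10": 120.0, "O3": 60.0})
        assert value == 120.0
        assert dominant == "PM10"

    def test_single_pollutant(self):
        assert haqi_overall({"SO2": 42.0}) == (42.0, "SO2")

    def test_tie_broken_by_fixed_order(self):
        value, dominant = haqi_overall({"O3": 90.0, "PM10": 90.0})
        assert dominant == "PM10"  # PM10 precedes O3 in the fixed order


class TestDrivers:
    def test_full_emission_attribution(self):
        idx15 = pd.date_range("2015-01-01", periods=10, freq="D")
        idx22 = pd.date_range("2022-01-01", periods=10, freq="D")
        obs = pd.concat([pd.Series(400.0, idx15), pd.Series(300.0, idx22)])
        shares = haqi_drivers(obs, obs.copy(), 2015, 2022)
        assert shares["emission_share_pct"] == pytest.approx(100.0)
        assert shares["met_share_pct"] == pytest.approx(0.0)

    def test_synthesized_deltas_give_93_percent(self):
        idx15 = pd.date_range("2015-01-01", periods=5, freq="D")
        idx22 = pd.date_range("2022-01-01", periods=5, freq="D")
        obs = pd.concat([pd.Series(445.0, idx15), pd.Series(262.0, idx22)])
        dew = pd.concat([pd.Series(440.0, idx15), pd.Series(269.81, idx22)])
        shares = haqi_drivers(obs, dew, 2015, 2022)
        # delta_obs = -183, delta_dew = -170.19 -> emission share 93%
        assert shares["emission_share_pct"] == pytest.approx(93.0, abs=0.01)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2015-01-01", "2016-12-31", freq="D")
        obs = pd.Series(rng.uniform(100, 400, len(idx)), index=idx)
        dew = pd.Series(rng.uniform(100, 400, len(idx)), index=idx)
        shares = haqi_drivers(obs, dew, 2015, 2016)
        assert shares["emission_share_pct"] + shares["met_share_pct"] == pytest.approx(100.0)


def test_relative_decline():
    assert relative_decline(445.0, 262.0) == pytest.approx(41.124, abs=0.001)
    with pytest.raises(ValueError):
        relative_decline(0.0, 10.0)


conc_strategy = st.tuples(
    st.floats(0.0, 500.0), st.floats(0.0, 400.0), st.floats(0.0, 300.0)
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(conc=conc_strategy)
def test_haqi_dominates_single_pollutant_aqi(conc):
    """RR' >= RR_i implies C'_i >= C_i, so the combined index dominates every
    conventional single-pollutant AQI."""
    frame = pd.DataFrame([dict(zip(["PM2.5", "O3", "SO2"], conc))],
                         index=pd.DatetimeIndex(["2020-01-01"]))
    _, overall = compute_haqi(frame, TOY_PARAMS)
    for p, c in zip(["PM2.5", "O3", "SO2"], conc):
        single = haqi_pollutant(c, TOY_PARAMS.ladders[p])
        assert overall["haqi"].iloc[0] >= single - 1e-9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(conc=conc_strategy, bump=st.floats(0.1, 200.0),
       which=st.integers(0, 2))
def test_haqi_monotone_in_each_concentration(conc, bump, which):
    pollutants = ["PM2.5", "O3", "SO2"]
    base = dict(zip(pollutants, conc))
    bumped = dict(base)
    bumped[pollutants[which]] += bump
    idx = pd.DatetimeIndex(["2020-01-01"])
    _, lo = compute_haqi(pd.DataFrame([base], index=idx), TOY_PARAMS)
    _, hi = compute_haqi(pd.DataFrame([bumped], index=idx), TOY_PARAMS)
    assert hi["haqi"].iloc[0] >= lo["haqi"].iloc[0] - 1e-9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(active=st.floats(100.0, 400.0), inert=st.floats(0.0, 1.0))
def test_pollutants_at_or_below_threshold_contribute_nothing(active, inert):
    """Removing a pollutant sitting at or below its no-effect threshold
    leaves the HAQI unchanged."""
    idx = pd.DatetimeIndex(["2020-01-01"])
    with_inert = pd.DataFrame([{"PM2.5": active, "O3": inert * 75.0}], index=idx)
    without = pd.DataFrame([{"PM2.5": active}], index=idx)
    params = HealthRiskParams(
        exposure={k: TOY_PARAMS.exposure[k] for k in ("PM2.5", "O3")},
        ladders={k: TOY_PARAMS.ladders[k] for k in ("PM2.5", "O3")},
    )
    _, a = compute_haqi(with_inert, params)
    _, b = compute_haqi(without, params)
    assert a["haqi"].iloc[0] == pytest.approx(b["haqi"].iloc[0], abs=1e-9)


def test_default_params_load_and_validate():
    params = HealthRiskParams.default()
    assert set(params.exposure) == {"PM2.5", "PM10", "NO2", "SO2", "O3", "CO"}
    for p, ladder in params.ladders.items():
        assert len(ladder.concentrations) == len(ladder.aqi)


def test_missing_beta_in_config_rejected():
    with pytest.raises(ValueError, match="missing health-risk key"):
        HealthRiskParams.from_dict(
            {"pollutants": {"PM2.5": {"c0": 10.0,
                                      "breakpoints": [35, 75],
                                      "aqi": [50, 100]}}})
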