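# metnorm

Meteorological normalization ("deweathering") of air-pollutant time series
with random forests, plus the analyses that sit on top of it: emission-vs-
meteorology trend attribution, a health-risk-based air quality index (HAQI),
and attributable premature mortality.

## The problem

Ambient concentrations of PM2.5, PM10, NO2, SO2, CO and O3 are driven by two
things: anthropogenic emissions and weather. A multi-year downward trend in
observed concentrations may overstate (or hide) the effect of emission
controls if meteorology also drifted over the period — deeper boundary
layers, stronger winds or wetter years all dilute pollution without any
emission change. `metnorm` separates the two drivers statistically, for
air-quality scientists and health-impact analysts who have monitoring data
but no up-to-date emission inventory to feed a chemical-transport model.

## The method

**Deweathering.** For each pollutant a random-forest regression predicts the
daily mean concentration from three time features — Unix time, Julian day,
and weekday, proxies for long-term, seasonal and weekly emission
variability — and fourteen daily meteorological features (U10, V10, T, BLH,
SR, TCC, TP, RH, U500, V500, W500, U850, V850, W850). The weather-normalized
concentration of day *t* is the arithmetic mean over many Monte Carlo passes
of the model prediction with day *t*'s time features but the complete met
row of a day drawn uniformly at random from a long historical climatology:

```
C_dew(t) = (1/N) Σ_k  f( time(t), met(d_k) ),   d_k ~ Uniform(climatology)
```

Whole met rows are drawn so cross-variable correlation is preserved. What
survives the averaging is the emission-driven signal.

**MET impact index.** For an averaging unit *i* (month, season, period):
`(C_obs,i − C_dew,i) / C_obs,i` — positive when meteorology worsened air
quality, negative when it helped.

**Trend attribution.** OLS slopes of annual means; the emission contribution
to an observed trend is `100 × slope_dew / slope_obs` (undefined when the
two disagree in sign).

**HAQI.** Per-pollutant relative risk `RR_i = exp(β_i (C_i − C0_i))` above a
no-effect threshold; total excess risk `ER = Σ (RR_i − 1)` and combined risk
`RR′ = ER + 1`; equivalent concentrations `C′_i = ln(RR′)/β_i + C0_i` mapped
through AQI breakpoint ladders; the overall HAQI is the maximum across
pollutants. Because `RR′ ≥ RR_i`, the HAQI dominates the conventional AQI.

**Mortality.** Per cause (stroke, IHD, COPD, LC for PM2.5; respiratory for
O3): `M = Y0 × Pop × (RR − 1)/RR`, with Y0 the baseline mortality rate and
`(RR − 1)/RR` the attribution fraction.

Everything is validated on synthetic data where the truth is known by
construction: `concentration = emission trend × weekday cycle × weather
response × noise`, with seasonal + AR(1) meteorology and an optional secular
met drift that confounds the raw trend.

## Worked example

The `demo` subcommand runs the whole chain on the default synthetic
scenario — eight years of daily PM2.5 (emission trend −5 % a⁻¹, confounded
by a deepening boundary layer) and O3 (+2 % a⁻¹) over a 2001–2022 synthetic
climatology, with 200 resampling passes:

```
$ metnorm demo --out demo_run --seed 1 --n-resamples 200
run complete; manifest at demo_run/manifest.json
  PM2.5: CV r=0.749 NMSE=0.094 RMSE=9.471
  O3: CV r=0.733 NMSE=0.048 RMSE=19.986
```

The fivefold-CV correlation around 0.75 and NMSE below 0.1 say the forests
explain most day-to-day variability. `demo_run/trends.csv` then shows, for
PM2.5 over the full window:

```
pollutant,period,observed_slope,...,deweathered_slope,...,contribution_pct
PM2.5,2015-2022,-3.037,...,-1.923,...,63
```

The raw observed slope (−3.04 units a⁻¹) is ~45 % steeper than the true
emission-only slope (−2.10 by construction) because the drifting boundary
layer adds a spurious decline; the deweathered slope (−1.92) recovers the
truth within ~9 %, and the emission contribution of 63 % quantifies how much
of the raw trend was real emission reduction. The manifest also records the
HAQI driver split (emission share ≈ 61 % of the HAQI change in this run) and
the deweathered avoided-deaths difference. Figures for annual means, the
monthly MET impact index, HAQI and mortality are written alongside.

The same stages are available piecemeal (`simulate`, `train`, `deweather`,
`impact`, `trends`, `haqi`, `mortality`) over the documented CSV schemas,
and as a library (`MeteoNormalizer`, a scikit-learn-style estimator with
`fit` / `predict` / `deweather`).

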