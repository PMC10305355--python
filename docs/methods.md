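# Methods

## Model and assumptions

`metnorm` treats a daily pollutant concentration as a function of slowly
varying emissions and fast-varying weather,

    C(t) ≈ f( U(t), J(t), W(t); M(t) )

learned by a random-forest regression. U (Unix time), J (Julian day) and
W (weekday, integer-coded Monday=0…Sunday=6) proxy long-term, seasonal and
weekly emission variability; M is the 14-component daily meteorological
state (near-surface winds, temperature, boundary-layer height, solar
radiation, cloud cover, precipitation, relative humidity, and 500/850-hPa
winds, in native ERA5-style units). The central assumptions are (i) the
emission signal is expressible through the three time features, (ii) the
climatology used for resampling is an unbiased sample of the weather the
site could have experienced, and (iii) weather affects concentrations
contemporaneously at daily resolution (no explicit multi-day transport
memory).

The weather-normalized value for day *t* averages model predictions over N
random draws of complete met rows from the climatology, holding the time
features fixed. Drawing whole rows preserves cross-variable correlation;
drawing variables independently would synthesize physically incoherent
weather and is deliberately not offered. Holding time features fixed is
essential: resampling them would average away exactly the emission signal
the procedure is meant to isolate. (Descriptions of this family of methods
occasionally say time variables are resampled too; that reading is
internally inconsistent with the method's purpose and is not implemented.
The choice is exposed only in documentation, not as a switch.)

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_estimators` | 300 | trees | conventional regression-forest size; skill plateaus well before this |
| `min_samples_leaf` | 5 | rows | standard regression default; limits variance without oversmoothing |
| `max_features` | ⌈p/3⌉ | features/split | the regression-forest convention |
| `train_fraction` | 0.70 | — | 70/30 train/holdout split of the input rows |
| `cv_folds` | 5 | — | fivefold cross-validation for the reported skill |
| `blocked_cv` | True | — | contiguous time-block folds limit autocorrelation leakage; random-row folds are an option |
| `n_resamples` | 1000 | passes | Monte Carlo error of the daily mean shrinks as 1/√N; 200 is enough for trend work (the demo default), 1000 for publication-grade daily series |
| `min_coverage` | 0.75 | fraction | a day needs ≥18 of 24 valid hours, a common regulatory completeness rule |

Blocked CV on a deterministic target measures mild extrapolation (each
contiguous fold contains met states whose exact anomalies were never seen);
random-row folds measure pure interpolation and score higher on noise-free
synthetic targets. Both are reported by the same `FitReport` machinery.

The skill metrics are Pearson r, RMSE, and NMSE = MSE / (mean(obs) ×
mean(pred)). A constant prediction has well-defined RMSE/NMSE but no
correlation; r is returned as NaN in that case rather than erroring, since
the numeric metrics remain meaningful.

## Synthetic data: what it emulates and what it does not

The generator produces daily meteorology as seasonal sinusoids plus AR(1)
anomalies (stationary initialization, per-variable ρ and innovation scale),
clipped for bounded quantities (TCC to [0,1], RH to [0,100]), with an
optional linear drift per variable referenced to the midpoint of the
generated period so a drifting variable's period mean stays at its
configured mean. Pollutants are `baseline × geometric emission trend ×
weekday multipliers × exp(Σ a_i z_i) × lognormal noise`, where the z_i are
met variables standardized by fixed configured centers/scales (so the truth
does not depend on the realized sample). The generator records every factor,
making reconstruction exact and parameter recovery scoreable against truth.

The default confounded scenario uses an emission trend of −5 % a⁻¹ on a
50 µg m⁻³ baseline over 2015–2022, day-to-day multiplicative noise of
σ = 0.25 (typical residual scatter for daily PM), a weather response
dominated by boundary-layer dilution (coefficient −0.30 per 150 m of BLH,
+0.12 per 8 K of T, −0.10 per 1.2 m s⁻¹ of 10-m wind speed), and a BLH
drift of +25 m a⁻¹ across the whole 2001–2022 history. The drift strength
was set by a design calculation, not by fitting: writing the observed slope
as d(E·w)/dt ≈ w̄·E′ + Ē·w′, a 25 m a⁻¹ drift makes the weather-driven
term roughly a third of the raw slope — the regime the normalization
exists for — while 12 m a⁻¹ would leave it near 25 %. It is deliberately
strong as a stress test, larger than real multi-decadal boundary-layer
trends.

What the synthetic data does **not** emulate: spatial structure, transport
episodes with multi-day memory in the pollutant itself (all persistence
lives in the met fields), chemistry couplings between pollutants, and
instrument artifacts. Passing the recovery test therefore shows the
statistical machinery isolates a multiplicative emission trend under
realistic seasonal/autocorrelated/drifting weather — not that any real
city's trend is correctly attributed.

## Numerical choices and degenerate inputs

- Trends are OLS on annual means (scipy's `linregress`, slope ± SE); the
  per-day Theil–Sen alternative was considered and not shipped — annual-mean
  OLS is what the reported per-year units imply, and the tests' independent
  oracle (centered normal equations) pins the arithmetic at 1e-10.
- Emission contributions are rounded half-up to integer percent; a
  sign-discordant slope pair yields an explicit `None` ("undefined"), and a
  zero observed slope raises.
- The MET impact index is computed from means at the aggregation level
  requested (month, season, period), never by averaging finer-level indexes:
  the ratio of means is not the mean of ratios, and a regression test guards
  the distinction. Error bars are across-year standard deviations.
- HAQI above the top breakpoint extrapolates the last segment's slope by
  default (capping at the top AQI is a config option); the first category
  uses the proportional rule AQI₁·C′/C₁. Ties for the dominant pollutant
  break in the fixed order PM2.5, PM10, O3, NO2, SO2, CO.
- Exposure–response constants (β, C0), breakpoint ladders, baseline
  mortality rates and population are configuration, not code. The shipped
  YAML defaults use the Chinese AQI standard's ladders and representative
  coefficients from the multi-city epidemiology literature; every
  correctness test supplies explicit toy values so no unstated constant is
  load-bearing.
- The leap-day rule in the lockdown sensitivity (2020 replaced by 2019,
  Feb 29 taking Feb 28) makes the two annual means equal only up to the
  duplicated day; exact equality holds after dropping Feb 29.
- Negative deweathered means are clipped at zero (a no-op in practice —
  forests cannot predict outside the trained range).
- O3 daily exposure defaults to the arithmetic daily mean for consistency
  with the other pollutants; the maximum daily 8-h mean is available
  (`metric="max8h"`), with the caveat that ozone health metrics are often
  seasonal/8-h based.
- Population is held at its base-year value across years, so mortality
  trends reflect exposure change, not demography.

## Known limitations

- **Edge attenuation.** Trees cannot extrapolate Unix time, so the first and
  last years of a deweathered series are pulled toward the interior,
  attenuating recovered trends by roughly 5–15 % on the default scenario —
  occasionally more when the realized anomalies make the drifting
  boundary layer especially collinear with time. This is intrinsic to
  tree-based normalization, not a bug; trend conclusions should weight the
  interior years.
- **Collinearity splitting.** When a met variable drifts secularly, the
  forest may attribute part of the emission trend to it (or vice versa);
  the recovery test quantifies the net effect but cannot remove it.
- The per-pollutant models are independent; no shared-weather joint fit.
- The HAQI's additive excess-risk combination is the only scheme
  implemented; multiplicative RR products and nonlinear
  concentration–response curves are out of scope, as are integrated
  exposure–response (GEMM/IER) mortality curves and age stratification.

## Problem sizes

The test suite trains small forests (20–100 trees) on 1–3 years of synthetic
data; the headline recovery test and the acceptance script use the full
8-year scenario with 300 trees and 200 resampling passes (~25 s on one CPU).
The demo uses 200 passes for the same reason; production runs would use the
1000-pass default.
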