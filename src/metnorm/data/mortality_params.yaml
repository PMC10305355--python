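# Default premature-mortality parameters.
#
# Cause-to-pollutant mapping: stroke, ischemic heart disease (IHD), chronic
# obstructive pulmonary disease (COPD) and lung cancer (LC) are linked to
# PM2.5; respiratory disease to O3.
#
# y0 is the cause-specific baseline mortality rate (deaths per person per
# year, Chinese yearbook scale); beta/c0 are log-linear approximations to
# long-term cohort exposure-response curves (per ug m-3). population is held
# at a 2015 value for a mid-size prefecture-level city. All of these are
# required configuration, not method constants: the tests use explicit toy
# values and real studies should supply their own yearbook numbers.
population: 4_470_000
causes:
  stroke:
    pollutant: PM2.5
    beta: 0.00130
    c0: 5.8
    y0: 0.00149
  IHD:
    pollutant: PM2.5
    beta: 0.00110
    c0: 5.8
    y0: 0.00122
  COPD:
    pollutant: PM2.5
    beta: 0.00080
    c0: 5.8
    y0: 0.00068
  LC:
    pollutant: PM2.5
    beta: 0.00095
    c0: 5.8
    y0: 0.00043
  respiratory:
    pollutant: O3
    beta: 0.00040
    c0: 70.0
    y0: 0.00078
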