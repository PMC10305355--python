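# Default health-risk parameters for the HAQI.
#
# Breakpoint ladders follow the Chinese AQI standard's daily tables
# (GB 3095-2012 / HJ 633-2012): concentration upper limits per health
# category mapped to AQI 50/100/150/200/300/400/500 (O3 uses the
# daily-max-8-h ladder, which the standard defines up to AQI 300).
#
# Exposure-response coefficients beta (per unit concentration: ug m-3,
# CO in mg m-3) and thresholds c0 are representative short-term mortality
# values from the Chinese multi-city epidemiology literature (the style of
# values used by health-risk AQI studies such as Hu et al. 2015). They are
# configuration, not constants of the method: swap this file to use a
# different epidemiological basis.
pollutants:
  PM2.5:
    beta: 0.00038
    c0: 15.0
    breakpoints: [35, 75, 115, 150, 250, 350, 500]
    aqi: [50, 100, 150, 200, 300, 400, 500]
  PM10:
    beta: 0.00032
    c0: 20.0
    breakpoints: [50, 150, 250, 350, 420, 500, 600]
    aqi: [50, 100, 150, 200, 300, 400, 500]
  NO2:
    beta: 0.0013
    c0: 10.0
    breakpoints: [40, 80, 180, 280, 565, 750, 940]
    aqi: [50, 100, 150, 200, 300, 400, 500]
  SO2:
    beta: 0.00081
    c0: 10.0
    breakpoints: [50, 150, 475, 800, 1600, 2100, 2620]
    aqi: [50, 100, 150, 200, 300, 400, 500]
  O3:
    beta: 0.00048
    c0: 75.0
    breakpoints: [100, 160, 215, 265, 800]
    aqi: [50, 100, 150, 200, 300]
  CO:
    beta: 0.037
    c0: 0.5
    breakpoints: [2, 4, 14, 24, 36, 48, 60]
    aqi: [50, 100, 150, 200, 300, 400, 500]
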