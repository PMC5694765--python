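# Default configuration: DICE-2013R climate parameters, the bundled
# business-as-usual scenario calibration, and pulse-experiment settings.
climate:
  f2x: 3.8        # W m-2 at doubled CO2
  ecs: 2.9        # degC equilibrium climate sensitivity
  b12: 0.088      # 5-yr atmosphere -> upper transfer fraction
  b23: 0.0025     # 5-yr upper -> deep transfer fraction
  mat_eq: 588.0   # GtC
  mu_eq: 1350.0   # GtC
  ml_eq: 10000.0  # GtC
  c1: 0.098       # 5-yr atmospheric temperature adjustment speed
  c3: 0.088       # atmosphere/deep-ocean heat exchange
  c4: 0.025       # 5-yr deep-ocean adjustment speed
  step_years: 5

bau:
  base_year: 2010
  horizon: 2300
  # Logistic emissions ramp (GtCO2/yr), chosen so the default climate module
  # reaches 4 degC above preindustrial in 2100; deterministic (no noise).
  emissions:
    peak_gtco2: 140.0
    midpoint_year: 2042
    timescale_yr: 30.0
    decline_start: 2150
    floor_frac: 0.25      # fraction of peak reached by the horizon
  # Exogenous non-CO2 forcing ramp (W m-2), DICE-2013R style.
  forcing_other:
    start_wm2: 0.25
    end_wm2: 0.70
    end_year: 2100
  economy:
    gdp0_usd: 65.0e+12      # global GDP in the base year
    gdp_growth0: 0.025      # initial growth rate, per year
    gdp_growth_decay: 0.004 # exponential decay of the growth rate
    pop0: 7.0e+9
    pop_max: 10.5e+9
    pop_timescale_yr: 40.0
    ag_share_range: [0.01, 0.08]  # per-region constant shares drawn once

scc:
  pulse_year: 2020
  pulse_gtco2: 1.0
  discount: 0.03
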