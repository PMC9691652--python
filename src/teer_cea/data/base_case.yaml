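# Base-case configuration: MitraClip + OMT vs. OMT alone, Chinese
# healthcare-payer perspective, 2021 CNY.
#
# Costs, utilities, transition matrices, CPI chain and analysis settings are
# the published inputs. Two blocks are NOT published and are produced by the
# calibration operation (teer_cea.economics.calibrate) against the reported
# lifetime outcomes (life-years 3.72/2.90, hospitalizations 1.16/1.51,
# QALYs 2.32/1.80, lifetime costs 423,817/28,369 CNY, ICER 754,410 CNY/QALY):
#   - decision_tree.initial_nyha_distribution (post-30-day NYHA shares)
#   - transitions.hospitalization (per-state monthly HF-hospitalization
#     probabilities)
# See analysis/01_calibrate.py and results/calibration.json for the fit.
costs:
  device: 322000.0
  procedure: 12172.0
  diagnosis: 16249.0
  medicine: 5018.0
  complications: 15070.0
  ward: 683.0
  nursing: 659.0
  others: 23808.0
  omt_monthly: 428.0
  hf_hospitalization: 10926.0
utilities:
  nyha1: 0.065
  nyha2: 0.065
  nyha3: 0.060
  nyha4: 0.055
  disutility_complications: 0.005
  disutility_procedure: 0.043
  disutility_hf_hospitalization: 0.10
  dead: 0.0
transitions:
  matrices:
    mitraclip:
      nyha1: [0.960, 0.040, 0.0, 0.0, 0.0]
      nyha2: [0.005, 0.945, 0.050, 0.0, 0.0]
      nyha3: [0.0, 0.025, 0.895, 0.070, 0.010]
      nyha4: [0.0, 0.0, 0.0, 0.800, 0.200]
    omt:
      nyha1: [0.950, 0.050, 0.0, 0.0, 0.0]
      nyha2: [0.010, 0.940, 0.040, 0.010, 0.0]
      nyha3: [0.0, 0.020, 0.920, 0.050, 0.010]
      nyha4: [0.0, 0.0, 0.0, 0.750, 0.250]
  hospitalization:  # calibrated (see header note)
    mitraclip:
      nyha1: 0.008919
      nyha2: 0.017839
      nyha3: 0.035678
      nyha4: 0.054508
    omt:
      nyha1: 0.010704
      nyha2: 0.026273
      nyha3: 0.052545
      nyha4: 0.105091
econ:
  annual_discount_rate: 0.05
  per_capita_gdp: 80976.0
  wtp_threshold: null  # derived: 3 x per-capita GDP = 242,928 CNY/QALY
  reporting_exchange_rate: 6.45
  source_exchange_rate: 6.75
  cpi_factors: [1.027, 1.038, 1.06, 1.043, 1.024, 1.018, 1.004]
decision_tree:
  initial_nyha_distribution:  # calibrated (see header note)
    mitraclip: [0.0, 0.965420, 0.034580, 0.0]
    omt: [0.0, 0.476394, 0.523606, 0.0]
  thirty_day_mortality:
    mitraclip: 0.0
    omt: 0.0
model:
  entry_age: 72.0
  terminal_age: 100.0
  cycle_length_months: 1
  half_cycle_correction: true
uncertainty:
  costs.device: {family: gamma, base: 322000.0, low: 161000.0, high: 386400.0}
  costs.procedure: {family: gamma, base: 12172.0, low: 6086.0, high: 24343.0}
  costs.diagnosis: {family: gamma, base: 16249.0, low: 8125.0, high: 32499.0}
  costs.medicine: {family: gamma, base: 5018.0, low: 2509.0, high: 10037.0}
  costs.complications: {family: gamma, base: 15070.0, low: 7535.0, high: 30140.0}
  costs.ward: {family: gamma, base: 683.0, low: 341.0, high: 1365.0}
  costs.nursing: {family: gamma, base: 659.0, low: 330.0, high: 1319.0}
  costs.others: {family: gamma, base: 23808.0, low: 11904.0, high: 47616.0}
  costs.omt_monthly: {family: gamma, base: 428.0, low: 214.0, high: 856.0}
  costs.hf_hospitalization: {family: gamma, base: 10926.0, low: 5463.0, high: 21852.0}
  utilities.nyha1: {family: beta, base: 0.065, low: 0.062, high: 0.068}
  utilities.nyha2: {family: beta, base: 0.065, low: 0.062, high: 0.068}
  utilities.nyha3: {family: beta, base: 0.060, low: 0.057, high: 0.063}
  utilities.nyha4: {family: beta, base: 0.055, low: 0.052, high: 0.058}
  utilities.disutility_complications: {family: beta, base: 0.005, low: 0.003, high: 0.007}
  utilities.disutility_procedure: {family: beta, base: 0.043, low: 0.034, high: 0.051}
  utilities.disutility_hf_hospitalization: {family: beta, base: 0.10, low: 0.08, high: 0.13}
  econ.annual_discount_rate: {family: fixed, base: 0.05, low: 0.0, high: 0.08}
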