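# Default polyp-surveillance de-escalation scenario, written out in full
# for reference. Every key is optional; an empty file gives exactly this.
schema_version: 1

standard_arm:
  label: 5-yearly surveillance
  start_age: 50
  interval: 5
  stop_age: 75

alternative_arm:
  label: 10-yearly surveillance
  start_age: 50
  interval: 10
  stop_age: 75

life_table:
  model: gompertz
  gompertz_a: 0.009      # hazard/yr at the reference age
  gompertz_b: 0.09       # log-hazard slope/yr
  reference_age: 50

natural_history:
  baseline_hazard_at_ref: 0.001
  baseline_doubling_years: 12
  reference_age: 50
  per_exam_protection: 0.5
  sensitivity_multiplier: 1.0
  excess_mortality_rate: 0.09
  cure_horizon: 5
  cycle_length: 0.08333333333333333   # 1 month
  horizon_age: 100
  horizon_years: 10
  discount_rate: 0

colonoscopy_burden:
  anxiety_duration: 21          # days
  anxiety_disutility: 0.1
  procedure_duration: 2         # days
  procedure_disutility: 0.5
  complication_qaly_loss: 14    # days per non-fatal complication
  fatal_complication_probability: 3.3333333333333335e-05   # 1/30000
  polypectomy_fraction: 0.3
  scaling: 1.0

complication_model:
  rate_at_40: 0.002
  rate_at_85: 0.038

treatment_disutility:
  initial_phase_disutility: 0.30
  continuing_phase_disutility: 0.10
  terminal_phase_disutility: 0.45

economics:
  cost_per_colonoscopy: 500
  cost_per_complication: 5000
  cost_crc_initial_per_year: 25000
  cost_crc_continuing_per_year: 2500
  cost_crc_terminal_per_year: 30000
  wtp: 20000

trial:
  p_S: 0.01
  alpha_one_sided: 0.05
  power: 0.90
  z_rounding: 3

sweep:
  disutility_scalings: [0.5, 0.8, 1.0, 1.2, 1.5]
  sensitivity_multipliers: [0.95, 1.0, 1.05]
  criterion: qaly
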