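# Bundled model configuration: UMEC/VI 62.5/25 ug vs tiotropium 18 ug in
# symptomatic COPD, Chinese healthcare-system perspective, 2020 USD.
# Health states: C = moderate (50% <= predicted FEV1 < 80%),
# B = severe (30-50%), A = very severe (<30%), DEATH absorbing.
# Transition probabilities are per 3-month cycle; Dirichlet counts are the
# per-destination pseudo-counts used for probabilistic sampling.
name: umec-vi-tio
currency: USD
price_year: 2020

model:
  horizon_cycles: 12
  cycle_years: 0.25
  discount_quarterly: 0.01
  gdp_per_capita: 10518.0
  wtp_per_qaly: 31554.0

# Replication conventions (see docs/methods.md). The published per-arm totals
# are reproduced with half-cycle correction, first-cycle-undiscounted
# exponents, no cycle-0 accrual, and the positional GOLD-stage assignment.
conventions:
  half_cycle: true
  discount_offset: 1
  cycle0_accrual: false
  gold_state_mapping: positional
  psa_shared_params: false
  nmb_tie_is_cost_effective: true

population:
  gold_stage_counts:
    UMEC_VI: {II: 395, III: 375, IV: 111}
    TIO: {II: 389, III: 376, IV: 106}

# rows: source state -> {destination: [probability, dirichlet_count]}
transitions:
  UMEC_VI:
    BASE:
      C: {C: [0.944, 1223], B: [0.030, 39], A: [0.000, 0], DEATH: [0.026, 34]}
      B: {C: [0.000, 0], B: [0.922, 1195], A: [0.030, 39], DEATH: [0.048, 62]}
      A: {C: [0.000, 0], B: [0.000, 0], A: [0.952, 1234], DEATH: [0.048, 62]}
    NEW:
      C: {C: [0.948, 1228], B: [0.026, 34], A: [0.000, 0], DEATH: [0.026, 34]}
      B: {C: [0.000, 0], B: [0.909, 1178], A: [0.043, 56], DEATH: [0.048, 62]}
      A: {C: [0.000, 0], B: [0.000, 0], A: [0.952, 1234], DEATH: [0.048, 62]}
  TIO:
    BASE:
      C: {C: [0.936, 818], B: [0.038, 33], A: [0.000, 0], DEATH: [0.026, 23]}
      B: {C: [0.000, 0], B: [0.911, 796], A: [0.041, 36], DEATH: [0.048, 42]}
      A: {C: [0.000, 0], B: [0.000, 0], A: [0.952, 832], DEATH: [0.048, 42]}
    NEW:
      C: {C: [0.948, 829], B: [0.026, 23], A: [0.000, 0], DEATH: [0.026, 23]}
      B: {C: [0.000, 0], B: [0.909, 794], A: [0.043, 38], DEATH: [0.048, 42]}
      A: {C: [0.000, 0], B: [0.000, 0], A: [0.952, 832], DEATH: [0.048, 42]}

# Per-cycle adverse-event probabilities: {event: [probability, gamma_shape]}.
# The gamma scale is point/shape (the printed 4-dp scale column rounds the
# smallest scales to zero, so it is reconstructed at full precision).
adverse_events:
  UMEC_VI:
    back_pain: [0.0154, 21.6629]
    cough: [0.0143, 142.2286]
    headache: [0.0470, 1803.471]
    nasopharyngitis: [0.0363, 50.4199]
    upper_respiratory_tract_infection: [0.0165, 123.5419]
  TIO:
    back_pain: [0.0161, 16.8545]
    cough: [0.0150, 183.1319]
    headache: [0.0320, 77.0869]
    nasopharyngitis: [0.0367, 499.4234]
    upper_respiratory_tract_infection: [0.0264, 44.4837]

# Costs in USD per quarter (drug, management) or per event (AE, exacerbation):
# {item: [point, uniform_low, uniform_high]}; bounds are the +/-20% rule.
costs:
  drug:
    UMEC_VI: [95.223, 76.1783, 114.2675]
    TIO: [180.528, 144.4223, 216.6334]
  management:
    C: [143.370, 114.6958, 172.0437]
    B: [204.289, 163.4312, 245.1468]
    A: [319.454, 255.5629, 383.3443]
  adverse_event:
    back_pain: [3.189, 2.5509, 3.8263]
    cough: [32.196, 25.7569, 38.6353]
    headache: [3.189, 2.5509, 3.8263]
    nasopharyngitis: [3.189, 2.5509, 3.8263]
    oropharyngeal_pain: [15.972, 12.7776, 19.1663]
    upper_respiratory_tract_infection: [39.214, 31.3711, 47.0566]
  exacerbation:
    severe: [2129.690, 1703.7522, 2555.6283]
    nonsevere: [44.824, 35.8594, 53.7891]

# Annual utility weights: {state: [point, beta_alpha, beta_beta]}
utilities:
  C: [0.810, 310.8375, 72.9125]
  B: [0.720, 160.5600, 62.4400]
  A: [0.670, 58.5848, 28.8552]

# Expected exacerbation counts per patient per 3-month cycle:
# {state: [point, uniform_low, uniform_high]}
exacerbations:
  severe:
    C: [0.028, 0.0220, 0.0330]
    B: [0.063, 0.0500, 0.0750]
    A: [0.135, 0.1080, 0.1620]
  nonsevere:
    C: [0.185, 0.1480, 0.2220]
    B: [0.273, 0.2180, 0.3270]
    A: [0.365, 0.2920, 0.4380]
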