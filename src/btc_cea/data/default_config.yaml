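# Base-case model configuration: XELOX vs GEMOX first-line chemotherapy for
# advanced biliary tract cancer, Chinese healthcare-payer perspective, 2020 USD.
# Every uncertain quantity is written as {value, low, high, dist}; dist is the
# sampling family used in probabilistic sensitivity analysis (beta | gamma);
# ranges are also the one-way sweep bounds.
settings:
  cycle_days: 21
  discount_annual: 0.05
  horizon_cycles: 174            # ~10 years; <0.5% of either cohort still alive
  bsa_m2: {value: 1.72, low: 1.376, high: 2.064, dist: fixed, psa: false}
  rounding_policy: fractional    # fractional | whole_unit (ceiling per administration)
  membership: start              # start | end | half  (cycle-membership timing)
  followup_scope: treatment      # treatment | all_pfs
  range_sd_rule: ci95            # ci95 (sd = width/3.92) | quarter (sd = width/4)
  wtp_per_qaly: [10438.41, 20876.83, 31315.24]   # 1x / 2x / 3x 2020 per-capita GDP

utilities:
  pfs: {value: 0.69, low: 0.455, high: 0.925, dist: beta}
  ps:  {value: 0.71, low: 0.455, high: 0.965, dist: beta}

survival:        # S(t) = exp(-lam * t^gamma), t in 21-day cycles
  XELOX:
    pfs: {lam: 0.201, gamma: 0.690}
    os:  {lam: 0.068, gamma: 0.958}
  GEMOX:
    pfs: {lam: 0.199, gamma: 0.739}
    os:  {lam: 0.038, gamma: 1.260}

drugs:           # unit pack prices; oxaliplatin is one shared parameter
  capecitabine: {unit_size_mg: 500,  unit_cost: {value: 3.19,   low: 2.55,   high: 3.83,   dist: gamma}}
  oxaliplatin:  {unit_size_mg: 50,   unit_cost: {value: 304.45, low: 243.56, high: 365.34, dist: gamma}}
  gemcitabine:  {unit_size_mg: 1000, unit_cost: {value: 229.94, low: 183.95, high: 275.93, dist: gamma}}

economics:
  administration_per_cycle: {value: 5.8, low: 4.64, high: 6.96, dist: gamma}
  followup_per_cycle:
    hospitalization: {value: 14.5,  low: 11.6,  high: 17.4,  dist: gamma}
    laboratory:      {value: 30.45, low: 24.36, high: 36.53, dist: gamma}
    ct_scan:         {value: 65.24, low: 52.19, high: 78.29, dist: gamma}
  bsc_per_cycle:  {value: 123.69,  low: 98.95,   high: 148.42,  dist: gamma}
  terminal_once:  {value: 1567.89, low: 1254.31, high: 1881.47, dist: gamma}

sae_unit_costs:  # USD per treated grade-3/4 event; stomatitis has no printed cost
  nausea:            {value: 66.34,   low: 53.07,   high: 79.61,   dist: gamma}
  vomiting:          {value: 66.34,   low: 53.07,   high: 79.61,   dist: gamma}
  diarrhea:          {value: 13.27,   low: 10.61,   high: 15.92,   dist: gamma}
  stomatitis:        {value: 0.0,     low: 0.0,     high: 0.0,     dist: gamma}
  hand_foot_syndrome: {value: 4.08,   low: 3.27,    high: 4.9,     dist: gamma}
  neutropenia:       {value: 3974.49, low: 3179.59, high: 4769.39, dist: gamma}
  neutropenic_fever: {value: 2231.69, low: 1785.35, high: 2678.03, dist: gamma}
  thrombocytopenia:  {value: 6526.06, low: 5220.85, high: 7831.27, dist: gamma}
  elevated_ast_alt:  {value: 60.22,   low: 48.17,   high: 72.26,   dist: gamma}
  asthenia:          {value: 3.06,    low: 2.45,    high: 3.67,    dist: gamma}
  anorexia:          {value: 26.54,   low: 21.23,   high: 31.84,   dist: gamma}

strategies:
  - name: XELOX
    max_treatment_cycles: 8
    regimen:
      # capecitabine 1,000 mg/m2 orally twice daily, days 1-14 of each cycle
      - {drug: capecitabine, dose_per_m2: 1000, administrations_per_cycle: 2, days_per_cycle_dosed: 14}
      # oxaliplatin 130 mg/m2 infusion, day 1
      - {drug: oxaliplatin, dose_per_m2: 130, administrations_per_cycle: 1, days_per_cycle_dosed: 1}
    sae_rates:   # grade-3/4 incidences; all assumed to occur in cycle 1
      stomatitis:        {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      hand_foot_syndrome: {value: 0.03, low: 0.024, high: 0.036, dist: beta}
      neutropenia:       {value: 0.04, low: 0.032, high: 0.048, dist: beta}
      thrombocytopenia:  {value: 0.09, low: 0.072, high: 0.108, dist: beta}
      asthenia:          {value: 0.02, low: 0.016, high: 0.024, dist: beta}
      anorexia:          {value: 0.02, low: 0.016, high: 0.024, dist: beta}
  - name: GEMOX
    max_treatment_cycles: 8
    regimen:
      # gemcitabine 1,000 mg/m2 infusion, days 1 and 8
      - {drug: gemcitabine, dose_per_m2: 1000, administrations_per_cycle: 2, days_per_cycle_dosed: 1}
      # oxaliplatin 100 mg/m2 infusion, day 1
      - {drug: oxaliplatin, dose_per_m2: 100, administrations_per_cycle: 1, days_per_cycle_dosed: 1}
    sae_rates:
      nausea:            {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      vomiting:          {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      diarrhea:          {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      stomatitis:        {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      neutropenia:       {value: 0.14, low: 0.112, high: 0.168, dist: beta}
      neutropenic_fever: {value: 0.01, low: 0.008, high: 0.012, dist: beta}
      thrombocytopenia:  {value: 0.11, low: 0.088, high: 0.132, dist: beta}
      elevated_ast_alt:  {value: 0.02, low: 0.016, high: 0.024, dist: beta}
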