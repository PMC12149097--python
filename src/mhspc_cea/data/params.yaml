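# Model parameters: 2024 USD, converted from CNY at 7.1954 CNY/USD.
# Each priced item carries value / low / high (one-way range) and the
# distribution used in probabilistic sensitivity analysis (gamma for
# costs, beta for utilities and the discount rate).
exchange_rate_cny_per_usd: 7.1954
wtp_usd_per_qaly: 37256.3

costs:   # USD per cycle unless noted
  rezvilutamide:        {value: 823.03,  low: 658.42,  high: 987.63,  dist: gamma}
  bicalutamide:         {value: 120.75,  low: 96.60,   high: 144.90,  dist: gamma}
  adt_average:          {value: 148.55,  low: 118.84,  high: 178.26,  dist: gamma}
  goserelin:            {value: 149.23,  low: 119.38,  high: 179.07,  dist: gamma}
  leuprolide:           {value: 176.86,  low: 141.49,  high: 212.23,  dist: gamma}
  triptorelin:          {value: 163.90,  low: 131.12,  high: 196.68,  dist: gamma}
  degarelix:            {value: 104.23,  low: 83.39,   high: 125.08,  dist: gamma}
  abiraterone:          {value: 177.89,  low: 142.31,  high: 213.47,  dist: gamma}
  enzalutamide:         {value: 1083.36, low: 866.69,  high: 1300.03, dist: gamma}
  docetaxel:            {value: 815.74,  low: 652.59,  high: 978.89,  dist: gamma}
  prednisone:           {value: 0.49,    low: 0.39,    high: 0.59,    dist: gamma}
  apalutamide:          {value: 917.25,  low: 733.80,  high: 1100.70, dist: gamma}
  darolutamide:         {value: 1044.00, low: 835.20,  high: 1252.80, dist: gamma}
  surgical_adt:         {value: 1389.78, low: 1111.82, high: 1667.73, dist: gamma}  # one-time, off by default
  routine_checklist:    {value: 642.89,  low: 514.32,  high: 771.47,  dist: gamma}  # per unit
  testosterone_test:    {value: 4.17,    low: 3.34,    high: 5.00,    dist: gamma}  # per unit
  psa_test:             {value: 16.68,   low: 13.34,   high: 20.01,   dist: gamma}  # per unit
  ct_scan:              {value: 27.80,   low: 22.24,   high: 33.35,   dist: gamma}  # per unit
  supportive_care:      {value: 117.1,   low: 93.68,   high: 140.52,  dist: gamma}
  follow_up:            {value: 51.5,    low: 41.2,    high: 61.8,    dist: gamma}  # per unit
  ae_hypertension:      {value: 12.15,   low: 9.72,    high: 14.58,   dist: gamma}  # per event
  ae_hypertriglyceridemia: {value: 13.23, low: 10.58,  high: 15.88,   dist: gamma}  # per event

utilities:
  pfs: {value: 0.76, low: 0.684, high: 0.836, dist: beta}
  pd:  {value: 0.68, low: 0.612, high: 0.748, dist: beta}

discount_rate: {value: 0.05, low: 0.00, high: 0.08, dist: beta}

# grade >= 3 treatment-emergent adverse-event incidence per arm (trial-level)
ae_incidence:
  rezvilutamide: {hypertension: 0.07, hypertriglyceridemia: 0.02}
  bicalutamide:  {hypertension: 0.08, hypertriglyceridemia: 0.07}

# share of progressed patients receiving active subsequent therapy
# (the remainder receive supportive care)
subsequent_uptake:
  rezvilutamide: 0.27
  bicalutamide: 0.62

# composition of the subsequent-therapy basket (weights sum to 1);
# prednisone is co-administered with abiraterone when enabled below
subsequent_basket:
  abiraterone: 0.3333333333333333
  enzalutamide: 0.3333333333333333
  docetaxel: 0.3333333333333334
abiraterone_includes_prednisone: true

# monitoring schedule: units consumed per 28-day cycle, by health state
monitoring:
  pfs:
    testosterone_test: 1.0
    psa_test: 1.0
    ct_scan: 0.3333333333333333   # one scan every 3 cycles
  pd:
    follow_up: 1.0

include_adt_in_pfs: true
end_of_life_cost: 0.0    # per death; no value published
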