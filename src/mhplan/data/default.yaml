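# Default study configuration: a Syria-like conflict-affected population, 2015
# reference year. Severity splits/disability weights follow GBD 2010 practice
# (PTSD uses the anxiety-disorders model as proxy). Care-package, staffing and
# intervention effect-size values are mhGAP-style defaults; values marked
# "derived" were calibrated once against the published headline outputs and
# are NOT source data.

seed: 20150101

fixture:
  total_population: 17054263.6   # anchored so 12.9% prevalence = 2.2M PTSD cases
  growth_rate: 0.025             # pyramid shape (quasi-stable intrinsic growth)
  peak_age: 25.0                 # prevalence curves peak in young adults
  spread: 15.0
  comorbid_rho: 0.50             # share of PTSD cases comorbid with depression
  mortality:
    makeham_a: 0.002
    gompertz_b: 5.0e-5
    gompertz_theta: 0.09

severity:
  depression:
    moderate_severe_prop: 0.28
    classes:
      - {name: asymptomatic, proportion: 0.13, dw: 0.0}
      - {name: mild, proportion: 0.59, dw: 0.159, dw_lower95: 0.107, dw_upper95: 0.223}
      - {name: moderate, proportion: 0.17, dw: 0.406, dw_lower95: 0.276, dw_upper95: 0.551}
      - {name: severe, proportion: 0.11, dw: 0.655, dw_lower95: 0.469, dw_upper95: 0.816}
  ptsd:  # anxiety-disorders severity model used as the PTSD proxy
    moderate_severe_prop: 0.30
    classes:
      - {name: asymptomatic, proportion: 0.14, dw: 0.0}
      - {name: mild, proportion: 0.56, dw: 0.030, dw_lower95: 0.018, dw_upper95: 0.046}
      - {name: moderate, proportion: 0.155, dw: 0.133, dw_lower95: 0.091, dw_upper95: 0.186}
      - {name: severe, proportion: 0.145, dw: 0.523, dw_lower95: 0.359, dw_upper95: 0.691}

# Care-package and staffing values below are mhGAP-style defaults; the
# visit/consultation rates and coverage targets are derived (calibrated once
# against the published baseline service contacts and FTE endpoints), not
# source data.
services:
  baseline_coverage: 0.01        # conservative current service coverage
  population_growth: 0.015       # projected annual growth over the horizon
  perinatal:
    fertility_rate: 0.11
    perinatal_depression_prev: 0.15
  packages:
    basic_psychosocial:          # advice, follow-up and community support contacts
      applies_to: [ptsd_only, depression_only, comorbid]
      coverage_target: 0.21      # derived
      treatments:
        ancillary: {proportion: 1.0, visits_per_person: 13.0, minutes_per_visit: 20}
    antidepressant_medication:
      applies_to: [ptsd_only, depression_only, comorbid]
      coverage_target: 0.45      # derived
      treatments:
        primary_care: {proportion: 0.8, visits_per_person: 7.7, minutes_per_visit: 15}
    intensive_psychosocial:      # specialist outpatient care, small inpatient use
      applies_to: [ptsd_only, depression_only, comorbid]
      coverage_target: 0.37      # derived
      treatments:
        outpatient: {proportion: 0.25, visits_per_person: 4.1, minutes_per_visit: 45}
        inpatient: {proportion: 0.025, bed_days_per_person: 13.0}
    perinatal_psychosocial:
      applies_to: [perinatal]
      coverage_target: 0.30
      treatments:
        primary_care: {proportion: 1.0, visits_per_person: 4.0, minutes_per_visit: 30}
        ancillary: {proportion: 1.0, visits_per_person: 6.0, minutes_per_visit: 20}
  staffing:
    ward_size_beds: 25
    occupancy_factor: 1.15       # 86% occupancy
    providers:                   # consults/day: brief primary-care contacts are
      psychiatrist:              # fast; ancillary outreach visits include travel
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 1.0
      other_physician:
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 1.0
      nurse:
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 10.0
      psychologist:
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 1.0
      other_psychosocial:
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 4.0
      other_provider:
        days_per_year: 230
        consults_per_day: {primary_care: 30, ancillary: 8.4, outpatient: 8}
        staff_per_ward: 4.0
    shares:                      # non-specialist-heavy delivery mix
      primary_care: {other_physician: 0.62, nurse: 0.20, other_provider: 0.18}
      ancillary: {nurse: 0.44, psychologist: 0.05, other_psychosocial: 0.28, other_provider: 0.23}
      outpatient: {psychiatrist: 0.55, psychologist: 0.30, other_physician: 0.15}

benefit:
  include_depression_only: true  # fold depression-only cases into the comorbid stream
  discount_rate: 0.03            # sensitivity analysis only; base case undiscounted
  streams:
    ptsd:
      remission: 0.17            # per person-year
      mortality_rr: 1.0          # case fatality assumed zero at all ages
      effects:                   # derived: calibrated against headline averted burden
        delta_remission: 0.22
        delta_dw: 0.885
      packages:
        - {name: basic_psychosocial, efficacy: 0.30, coverage_share: 1.0}
        - {name: antidepressant_medication, efficacy: 0.25, coverage_share: 0.8}
        - {name: intensive_psychosocial, efficacy: 0.40, coverage_share: 0.3}
    comorbid:
      remission: 1.40            # per person-year (mean duration ~37.7 weeks)
      mortality_rr: 1.9
      effects:                   # derived: calibrated against headline averted burden
        delta_remission: 0.22
        delta_dw: 0.885
      packages:
        - {name: basic_psychosocial, efficacy: 0.30, coverage_share: 1.0}
        - {name: antidepressant_medication, efficacy: 0.25, coverage_share: 0.8}
        - {name: intensive_psychosocial, efficacy: 0.40, coverage_share: 0.3}
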