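output_dir: output
seed: 1
generator:
  n_individuals: 5000
  horizon: 12.5
  seed: 0
  exposure_model:
    intercept: 1.7
    field_vocational: -1.3
    iq_stanine_band_1_3: -1.3
    iq_stanine_band_7_9: 0.9
    parental_education_lower_secondary: -0.7
    parental_education_university: 0.6
    parental_income_band_lt60: -0.5
    parental_income_band_gt140: 0.4
    parental_disability_yes: -0.4
    mother_marital_status_not_married: -0.6
    mother_marital_status_separated: -0.5
    mother_marital_status_other: -0.3
    childhood_chronic_disease_basic: -0.7
    childhood_chronic_disease_attendance: -0.6
    military_eligibility_issues: -1.0
    district_unemployment_rate: -0.05
  gap_rate: 0.04
  overlap_rate: 0.15
  exclusion_fractions:
    pre_start_emigration: 0.02
    no_upper_secondary_start: 0.038
    missing_conscript_data: 0.03
    missing_parental_sep: 0.02
    starts_in_disability: 0.002
    only_paternal_leave: 0.001
  covariate_marginals:
    birth_year:
    - 0.18
    - 0.18
    - 0.16
    - 0.16
    - 0.16
    - 0.16
    parental_education:
    - 0.6
    - 0.11
    - 0.29
    parental_income_band:
    - 0.39
    - 0.12
    - 0.34
    - 0.15
    parental_disability:
    - 0.71
    - 0.29
    mother_marital_status:
    - 0.75
    - 0.02
    - 0.15
    - 0.08
    childhood_chronic_disease:
    - 0.99
    - 0.005
    - 0.005
    iq_stanine_band:
    - 0.58
    - 0.16
    - 0.26
    bmi_band:
    - 0.79
    - 0.05
    - 0.13
    - 0.03
    military_eligibility:
    - 0.98
    - 0.02
  general_fraction: 0.403
  unemployment_rate_mean_sd:
  - 2.8
  - 1.4
  intensity_spec:
    breakpoints:
    - 0.0
    - 3.0
    - 6.0
    baseline_hazards:
      work->unemployment:
      - 0.12
      - 0.07
      - 0.05
      work->education:
      - 0.1
      - 0.05
      - 0.02
      work->sick_leave:
      - 0.06
      - 0.08
      - 0.08
      unemployment->work:
      - 0.6
      - 0.5
      - 0.45
      unemployment->education:
      - 0.15
      - 0.08
      - 0.03
      unemployment->sick_leave:
      - 0.08
      - 0.08
      - 0.08
      unemployment->disability:
      - 0.01
      - 0.015
      - 0.02
      education->work:
      - 0.35
      - 0.45
      - 0.5
      education->unemployment:
      - 0.08
      - 0.07
      - 0.06
      education->sick_leave:
      - 0.03
      - 0.04
      - 0.05
      sick_leave->work:
      - 0.5
      - 0.45
      - 0.4
      sick_leave->unemployment:
      - 0.1
      - 0.1
      - 0.1
      sick_leave->education:
      - 0.05
      - 0.03
      - 0.01
      sick_leave->disability:
      - 0.01
      - 0.02
      - 0.03
    log_hazard_ratios:
      work->unemployment:
        exposure: -0.51
        iq_stanine_band_1_3: 0.45
        iq_stanine_band_7_9: -0.25
        parental_education_lower_secondary: 0.3
        parental_education_university: -0.2
      work->sick_leave:
        exposure: -0.56
        iq_stanine_band_1_3: 0.4
        parental_education_lower_secondary: 0.25
      work->education:
        exposure: 0.64
        iq_stanine_band_7_9: 0.4
        parental_education_university: 0.35
      unemployment->work:
        exposure: 0.18
        iq_stanine_band_1_3: -0.25
      unemployment->sick_leave:
        exposure: -0.31
        iq_stanine_band_1_3: 0.3
      unemployment->education:
        exposure: 0.92
        parental_education_university: 0.3
      unemployment->disability:
        exposure: -0.5
        iq_stanine_band_1_3: 0.4
      sick_leave->work:
        exposure: 0.27
      sick_leave->unemployment:
        exposure: -0.12
      sick_leave->education:
        exposure: 1.1
      sick_leave->disability:
        exposure: -0.4
        iq_stanine_band_1_3: 0.35
      education->work:
        exposure: 0.11
      education->unemployment:
        exposure: -0.22
        iq_stanine_band_1_3: 0.25
      education->sick_leave:
        exposure: -0.3
    initial_state_logits:
      unemployment:
        intercept: -1.6
        exposure: -0.6
        iq_stanine_band_1_3: 0.5
      education:
        intercept: -1.4
        exposure: 1.6
        field_vocational: -1.7
        parental_education_university: 0.5
      sick_leave:
        intercept: -2.6
        exposure: -0.4
    sojourn_multipliers: {}
spells_path: null
cohort_path: null
fields:
- general
- vocational
analyses:
- unadjusted
- cox_conditional
- iptw
patterns:
  unfavourable:
    iq_stanine_band: '1_3'
    parental_education: lower_secondary
    parental_income_band: lt60
  favourable:
    iq_stanine_band: '7_9'
    parental_education: university
    parental_income_band: gt140
income_threshold_G: 2.0
stabilized_weights: false
truncate_weight_percentiles: null
make_plots: false
bootstrap: null
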