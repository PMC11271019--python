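# Default report configuration for unblinded data: summary statistics
# are split by the treatment variable. Override any key in a study
# config; unknown keys are rejected to surface typos.
study_id: STUDY
cutoff_date: null
blinded: false
treatment_var: ARM
subject_id_var: USUBJID
population: all_dm
severity_order: [MILD, MODERATE, SEVERE]
teae_lag_days: 30
visit_window_days: 3
required_variables:
  DM: [USUBJID, AGE, SEX, ARM, RFSTDTC]
  AE: [USUBJID, AEDECOD, AEBODSYS, AESEV, AESTDTC]
  LB: [USUBJID, LBTESTCD, LBORRES, VISITNUM, LBDTC]
  EG: [USUBJID, EGTESTCD, EGORRES, VISITNUM, EGDTC]
  VS: [USUBJID, VSTESTCD, VSORRES, VISITNUM, VSDTC]
  EX: [USUBJID, EXSTDTC, EXENDTC]
  DS: [USUBJID, DSDECOD, DSSTDTC]
  SV: [USUBJID, VISITNUM, SVSTDTC]
diff_keys:
  AE: [USUBJID, AEDECOD, AESTDTC, AESEQ]
  LB: [USUBJID, LBTESTCD, VISITNUM]
  EG: [USUBJID, EGTESTCD, VISITNUM]
  VS: [USUBJID, VSTESTCD, VISITNUM]
  DM: [USUBJID]
  DS: [USUBJID, DSDECOD]
  SV: [USUBJID, VISITNUM]
  EX: [USUBJID, EXSTDTC]
profiles:
  page_height_units: 10.0
  modules:
    - kind: text
      domain: DM
      title: Demographics
      variables: [AGE, SEX, RACE, COUNTRY]
    - kind: interval
      domain: EX
      title: Treatment exposure
      label_var: EXTRT
      start_var: EXSTDTC
      end_var: EXENDTC
    - kind: interval
      domain: AE
      title: Adverse events
      label_var: AEDECOD
      start_var: AESTDTC
      end_var: AEENDTC
    - kind: event
      domain: DS
      title: Disposition
      label_var: DSDECOD
      date_var: DSSTDTC
    - kind: line
      domain: LB
      title: Laboratory
      parameter_var: LBTESTCD
      result_var: LBORRES
      date_var: LBDTC
      low_var: LBORNRLO
      high_var: LBORNRHI
chapters:
  - id: disposition
    template: disposition
    title: Subject disposition
    output: disposition
    params:
      dataset: DS
      visits_dataset: SV
  - id: demography
    template: demography
    title: Demographic characteristics
    output: demography
    params:
      dataset: DM
      categorical_vars: [SEX, RACE, COUNTRY]
      continuous_vars: [AGE]
  - id: adverse-events
    template: adverse_events
    title: Adverse events
    output: adverse_events
    params:
      dataset: AE
      exposure_dataset: EX
      treatment_emergent: true
  - id: labs
    template: labs
    title: Laboratory safety
    output: labs
    params:
      dataset: LB
      parameters: [ALT, BILI, CREAT]
      edish: true
      alt_code: ALT
      bili_code: BILI
      shift: true
      spaghetti: true
  - id: batch-comparison
    template: batch_comparison
    title: Comparison with previous batch
    output: batch_comparison
    params:
      dataset: AE
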