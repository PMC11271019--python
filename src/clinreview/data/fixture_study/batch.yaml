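batch_id: FIX01-B1
cutoff_date: '2023-05-16'
blinded: false
treatment_var: ARM
domains:
  DM: dm.csv
  SV: sv.csv
  EX: ex.csv
  DS: ds.csv
  LB: lb.csv
  EG: eg.csv
  VS: vs.csv
  AE: ae.csv
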