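STUDYID,USUBJID,DSDECOD,DSSTDTC
FIX01,FIX01-0001,COMPLETED,2023-03-27
FIX01,FIX01-0002,COMPLETED,2023-03-24
FIX01,FIX01-0003,COMPLETED,2023-03-23
FIX01,FIX01-0004,COMPLETED,2023-05-09
FIX01,FIX01-0005,ADVERSE EVENT,2023-03-27
FIX01,FIX01-0006,COMPLETED,2023-04-28
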