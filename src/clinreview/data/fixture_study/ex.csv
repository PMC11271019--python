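STUDYID,USUBJID,EXTRT,EXDOSE,EXDOSU,EXSTDTC,EXENDTC
FIX01,FIX01-0001,STUDY DRUG,50,mg,2023-01-15,2023-03-27
FIX01,FIX01-0002,STUDY DRUG,50,mg,2023-01-12,2023-03-24
FIX01,FIX01-0003,STUDY DRUG,50,mg,2023-01-12,2023-03-23
FIX01,FIX01-0004,STUDY DRUG,50,mg,2023-03-01,2023-05-09
FIX01,FIX01-0005,STUDY DRUG,50,mg,2023-02-27,2023-03-27
FIX01,FIX01-0006,STUDY DRUG,50,mg,2023-02-17,2023-04-28
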