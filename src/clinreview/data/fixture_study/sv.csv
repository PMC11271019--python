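STUDYID,USUBJID,VISITNUM,VISIT,SVSTDTC
FIX01,FIX01-0001,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,6,VISIT 6,2023-03-27
FIX01,FIX01-0002,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,6,VISIT 6,2023-03-24
FIX01,FIX01-0003,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,6,VISIT 6,2023-03-23
FIX01,FIX01-0004,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,6,VISIT 6,2023-05-09
FIX01,FIX01-0005,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,3,VISIT 3,2023-03-27
FIX01,FIX01-0006,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,6,VISIT 6,2023-04-28
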