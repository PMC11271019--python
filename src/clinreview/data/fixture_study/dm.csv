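STUDYID,USUBJID,AGE,SEX,RACE,COUNTRY,ARM,RFSTDTC
FIX01,FIX01-0001,45,F,WHITE,FRA,Active,2023-01-15
FIX01,FIX01-0002,57,F,BLACK OR AFRICAN AMERICAN,DEU,Active,2023-01-12
FIX01,FIX01-0003,74,M,BLACK OR AFRICAN AMERICAN,FRA,Active,2023-01-12
FIX01,FIX01-0004,42,F,BLACK OR AFRICAN AMERICAN,BEL,Placebo,2023-03-01
FIX01,FIX01-0005,78,M,WHITE,DEU,Placebo,2023-02-27
FIX01,FIX01-0006,47,F,ASIAN,NLD,Placebo,2023-02-17
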