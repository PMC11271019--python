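STUDYID,USUBJID,AESEQ,AEDECOD,AEBODSYS,AESEV,AESER,AESTDTC,AEENDTC
FIX01,FIX01-0001,1,RASH,SKIN AND SUBCUTANEOUS TISSUE DISORDERS,MILD,N,2023-01-16,
FIX01,FIX01-0001,2,URINARY TRACT INFECTION,INFECTIONS AND INFESTATIONS,MILD,N,2023-03,
FIX01,FIX01-0002,1,SOMNOLENCE,NERVOUS SYSTEM DISORDERS,MILD,N,2023-02-10,
FIX01,FIX01-0002,2,DIZZINESS,NERVOUS SYSTEM DISORDERS,MILD,N,2023-03-09,
FIX01,FIX01-0002,3,CHILLS,GENERAL DISORDERS,MILD,N,2023-03-26,2023-04-14
FIX01,FIX01-0003,1,HEADACHE,NERVOUS SYSTEM DISORDERS,MILD,N,2022-12-25,
FIX01,FIX01-0003,2,VOMITING,GASTROINTESTINAL DISORDERS,MILD,N,2023-01-13,2023-01-29
FIX01,FIX01-0003,3,CHILLS,GENERAL DISORDERS,MODERATE,N,2023-03-12,2023-03-22
FIX01,FIX01-0005,1,CHILLS,GENERAL DISORDERS,MODERATE,N,2023-02-05,2023-02-15
FIX01,FIX01-0005,2,CHILLS,GENERAL DISORDERS,MILD,N,2023-03-01,2023-03-20
FIX01,FIX01-0005,3,PRURITUS,SKIN AND SUBCUTANEOUS TISSUE DISORDERS,MODERATE,N,2023-03-29,
FIX01,FIX01-0006,1,RASH,SKIN AND SUBCUTANEOUS TISSUE DISORDERS,MILD,N,2023-02-18,
FIX01,FIX01-0006,2,SOMNOLENCE,NERVOUS SYSTEM DISORDERS,MILD,N,2023-04-28,
FIX01,FIX01-0001,3,HEPATOTOXICITY,HEPATOBILIARY DISORDERS,MILD,N,2023-01-20,
FIX01,FIX01-0001,4,HEPATOTOXICITY,HEPATOBILIARY DISORDERS,SEVERE,Y,2023-01-20,
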