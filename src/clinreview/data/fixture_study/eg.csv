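STUDYID,USUBJID,EGTESTCD,EGTEST,EGORRES,EGORRESU,EGREPNUM,VISITNUM,VISIT,EGDTC
FIX01,FIX01-0001,QT,QT Interval,382.0,ms,1,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,HR,Heart Rate,64.0,beats/min,1,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,QT,QT Interval,400.0,ms,1,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,HR,Heart Rate,83.0,beats/min,1,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,QT,QT Interval,389.0,ms,1,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,HR,Heart Rate,64.0,beats/min,1,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,QT,QT Interval,397.0,ms,1,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,HR,Heart Rate,72.0,beats/min,1,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,QT,QT Interval,389.0,ms,2,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,HR,Heart Rate,75.0,beats/min,2,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,QT,QT Interval,396.0,ms,1,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,HR,Heart Rate,70.0,beats/min,1,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,QT,QT Interval,368.0,ms,1,6,VISIT 6,2023-03-27
FIX01,FIX01-0001,HR,Heart Rate,70.0,beats/min,1,6,VISIT 6,2023-03-27
FIX01,FIX01-0002,QT,QT Interval,405.0,ms,1,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,HR,Heart Rate,57.0,beats/min,1,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,QT,QT Interval,411.0,ms,1,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,HR,Heart Rate,75.0,beats/min,1,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,QT,QT Interval,380.0,ms,2,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,HR,Heart Rate,78.0,beats/min,2,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,QT,QT Interval,388.0,ms,1,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,HR,Heart Rate,86.0,beats/min,1,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,QT,QT Interval,381.0,ms,1,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,HR,Heart Rate,68.0,beats/min,1,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,QT,QT Interval,387.0,ms,1,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,HR,Heart Rate,63.0,beats/min,1,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,QT,QT Interval,429.0,ms,1,6,VISIT 6,2023-03-24
FIX01,FIX01-0002,HR,Heart Rate,51.0,beats/min,1,6,VISIT 6,2023-03-24
FIX01,FIX01-0003,QT,QT Interval,388.0,ms,1,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,HR,Heart Rate,78.0,beats/min,1,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,QT,QT Interval,412.0,ms,1,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,HR,Heart Rate,73.0,beats/min,1,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,QT,QT Interval,412.0,ms,2,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,HR,Heart Rate,80.0,beats/min,2,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,QT,QT Interval,402.0,ms,1,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,HR,Heart Rate,71.0,beats/min,1,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,QT,QT Interval,400.0,ms,2,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,HR,Heart Rate,54.0,beats/min,2,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,QT,QT Interval,407.0,ms,1,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,HR,Heart Rate,87.0,beats/min,1,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,QT,QT Interval,421.0,ms,1,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,HR,Heart Rate,88.0,beats/min,1,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,QT,QT Interval,427.0,ms,2,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,HR,Heart Rate,75.0,beats/min,2,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,QT,QT Interval,405.0,ms,1,6,VISIT 6,2023-03-23
FIX01,FIX01-0003,HR,Heart Rate,88.0,beats/min,1,6,VISIT 6,2023-03-23
FIX01,FIX01-0004,QT,QT Interval,416.0,ms,1,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,HR,Heart Rate,74.0,beats/min,1,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,QT,QT Interval,396.0,ms,1,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,HR,Heart Rate,69.0,beats/min,1,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,QT,QT Interval,407.0,ms,1,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,HR,Heart Rate,68.0,beats/min,1,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,QT,QT Interval,415.0,ms,1,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,HR,Heart Rate,74.0,beats/min,1,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,QT,QT Interval,393.0,ms,1,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,HR,Heart Rate,55.0,beats/min,1,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,QT,QT Interval,408.0,ms,1,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,HR,Heart Rate,95.0,beats/min,1,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,QT,QT Interval,368.0,ms,2,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,HR,Heart Rate,74.0,beats/min,2,6,VISIT 6,2023-05-09
FIX01,FIX01-0005,QT,QT Interval,414.0,ms,1,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,HR,Heart Rate,69.0,beats/min,1,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,QT,QT Interval,426.0,ms,2,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,HR,Heart Rate,67.0,beats/min,2,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,QT,QT Interval,403.0,ms,1,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,HR,Heart Rate,62.0,beats/min,1,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,QT,QT Interval,405.0,ms,1,3,VISIT 3,2023-03-27
FIX01,FIX01-0005,HR,Heart Rate,75.0,beats/min,1,3,VISIT 3,2023-03-27
FIX01,FIX01-0006,QT,QT Interval,417.0,ms,1,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,HR,Heart Rate,64.0,beats/min,1,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,QT,QT Interval,377.0,ms,1,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,HR,Heart Rate,74.0,beats/min,1,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,QT,QT Interval,407.0,ms,1,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,HR,Heart Rate,68.0,beats/min,1,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,QT,QT Interval,423.0,ms,2,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,HR,Heart Rate,71.0,beats/min,2,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,QT,QT Interval,408.0,ms,1,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,HR,Heart Rate,71.0,beats/min,1,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,QT,QT Interval,383.0,ms,1,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,HR,Heart Rate,96.0,beats/min,1,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,QT,QT Interval,398.0,ms,1,6,VISIT 6,2023-04-28
FIX01,FIX01-0006,HR,Heart Rate,71.0,beats/min,1,6,VISIT 6,2023-04-28
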