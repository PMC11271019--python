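STUDYID,USUBJID,VSTESTCD,VSTEST,VSORRES,VSORRESU,VISITNUM,VISIT,VSDTC
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,109.0,mmHg,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,78.0,mmHg,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,111.0,mmHg,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,75.0,mmHg,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,114.0,mmHg,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,90.0,mmHg,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,107.0,mmHg,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,79.0,mmHg,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,116.0,mmHg,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,92.0,mmHg,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,SYSBP,Systolic Blood Pressure,126.0,mmHg,6,VISIT 6,2023-03-27
FIX01,FIX01-0001,DIABP,Diastolic Blood Pressure,71.0,mmHg,6,VISIT 6,2023-03-27
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,127.0,mmHg,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,85.0,mmHg,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,146.0,mmHg,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,80.0,mmHg,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,114.0,mmHg,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,75.0,mmHg,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,122.0,mmHg,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,79.0,mmHg,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,133.0,mmHg,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,77.0,mmHg,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,SYSBP,Systolic Blood Pressure,109.0,mmHg,6,VISIT 6,2023-03-24
FIX01,FIX01-0002,DIABP,Diastolic Blood Pressure,79.0,mmHg,6,VISIT 6,2023-03-24
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,122.0,mmHg,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,77.0,mmHg,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,121.0,mmHg,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,81.0,mmHg,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,128.0,mmHg,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,85.0,mmHg,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,118.0,mmHg,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,75.0,mmHg,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,148.0,mmHg,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,74.0,mmHg,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,SYSBP,Systolic Blood Pressure,129.0,mmHg,6,VISIT 6,2023-03-23
FIX01,FIX01-0003,DIABP,Diastolic Blood Pressure,96.0,mmHg,6,VISIT 6,2023-03-23
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,116.0,mmHg,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,83.0,mmHg,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,120.0,mmHg,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,84.0,mmHg,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,125.0,mmHg,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,70.0,mmHg,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,123.0,mmHg,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,79.0,mmHg,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,110.0,mmHg,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,89.0,mmHg,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,SYSBP,Systolic Blood Pressure,121.0,mmHg,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,DIABP,Diastolic Blood Pressure,64.0,mmHg,6,VISIT 6,2023-05-09
FIX01,FIX01-0005,SYSBP,Systolic Blood Pressure,133.0,mmHg,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,DIABP,Diastolic Blood Pressure,67.0,mmHg,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,SYSBP,Systolic Blood Pressure,118.0,mmHg,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,DIABP,Diastolic Blood Pressure,93.0,mmHg,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,SYSBP,Systolic Blood Pressure,143.0,mmHg,3,VISIT 3,2023-03-27
FIX01,FIX01-0005,DIABP,Diastolic Blood Pressure,83.0,mmHg,3,VISIT 3,2023-03-27
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,138.0,mmHg,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,90.0,mmHg,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,109.0,mmHg,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,72.0,mmHg,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,129.0,mmHg,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,90.0,mmHg,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,116.0,mmHg,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,79.0,mmHg,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,137.0,mmHg,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,76.0,mmHg,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,SYSBP,Systolic Blood Pressure,108.0,mmHg,6,VISIT 6,2023-04-28
FIX01,FIX01-0006,DIABP,Diastolic Blood Pressure,69.0,mmHg,6,VISIT 6,2023-04-28
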