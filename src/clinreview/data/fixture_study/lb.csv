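STUDYID,USUBJID,LBTESTCD,LBTEST,LBORRES,LBORRESU,LBORNRLO,LBORNRHI,VISITNUM,VISIT,LBDTC
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,20.1,U/L,7.0,44.0,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,BILI,Bilirubin,24.7,umol/L,3.0,21.0,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,CREAT,Creatinine,60.3,umol/L,49.0,90.0,1,VISIT 1,2023-01-15
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,176.0,U/L,7.0,44.0,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,BILI,Bilirubin,63.0,umol/L,3.0,21.0,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,CREAT,Creatinine,58.5,umol/L,49.0,90.0,2,VISIT 2,2023-01-29
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,10.4,U/L,7.0,44.0,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,BILI,Bilirubin,20.7,umol/L,3.0,21.0,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,CREAT,Creatinine,45.8,umol/L,49.0,90.0,3,VISIT 3,2023-02-11
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,25.2,U/L,7.0,44.0,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,BILI,Bilirubin,0.4,umol/L,3.0,21.0,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,CREAT,Creatinine,58.9,umol/L,49.0,90.0,4,VISIT 4,2023-02-25
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,48.5,U/L,7.0,44.0,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,BILI,Bilirubin,26.5,umol/L,3.0,21.0,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,CREAT,Creatinine,41.5,umol/L,49.0,90.0,5,VISIT 5,2023-03-13
FIX01,FIX01-0001,ALT,Alanine Aminotransferase,44.7,U/L,7.0,44.0,6,VISIT 6,2023-03-27
FIX01,FIX01-0001,BILI,Bilirubin,18.4,umol/L,3.0,21.0,6,VISIT 6,2023-03-27
FIX01,FIX01-0001,CREAT,Creatinine,40.6,umol/L,49.0,90.0,6,VISIT 6,2023-03-27
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,32.0,U/L,7.0,44.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,BILI,Bilirubin,13.6,umol/L,3.0,21.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,CREAT,Creatinine,86.0,umol/L,49.0,90.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,22.5,U/L,7.0,44.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,BILI,Bilirubin,13.3,umol/L,3.0,21.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,CREAT,Creatinine,103.9,umol/L,49.0,90.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,5.2,U/L,7.0,44.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,BILI,Bilirubin,6.1,umol/L,3.0,21.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,CREAT,Creatinine,46.2,umol/L,49.0,90.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,26.4,U/L,7.0,44.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,BILI,Bilirubin,20.4,umol/L,3.0,21.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,CREAT,Creatinine,70.1,umol/L,49.0,90.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,37.1,U/L,7.0,44.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,BILI,Bilirubin,13.2,umol/L,3.0,21.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,CREAT,Creatinine,56.4,umol/L,49.0,90.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0002,ALT,Alanine Aminotransferase,36.0,U/L,7.0,44.0,6,VISIT 6,2023-03-24
FIX01,FIX01-0002,BILI,Bilirubin,14.0,umol/L,3.0,21.0,6,VISIT 6,2023-03-24
FIX01,FIX01-0002,CREAT,Creatinine,89.2,umol/L,49.0,90.0,6,VISIT 6,2023-03-24
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,3.2,U/L,7.0,44.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,BILI,Bilirubin,13.2,umol/L,3.0,21.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,CREAT,Creatinine,69.6,umol/L,49.0,90.0,1,VISIT 1,2023-01-12
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,31.4,U/L,7.0,44.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,BILI,Bilirubin,0.4,umol/L,3.0,21.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,CREAT,Creatinine,91.1,umol/L,49.0,90.0,2,VISIT 2,2023-01-25
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,43.0,U/L,7.0,44.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,BILI,Bilirubin,17.3,umol/L,3.0,21.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,CREAT,Creatinine,104.0,umol/L,49.0,90.0,3,VISIT 3,2023-02-09
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,34.7,U/L,7.0,44.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,BILI,Bilirubin,16.9,umol/L,3.0,21.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,CREAT,Creatinine,46.6,umol/L,49.0,90.0,4,VISIT 4,2023-02-24
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,10.9,U/L,7.0,44.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,BILI,Bilirubin,0.6,umol/L,3.0,21.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,CREAT,Creatinine,100.4,umol/L,49.0,90.0,5,VISIT 5,2023-03-09
FIX01,FIX01-0003,ALT,Alanine Aminotransferase,27.9,U/L,7.0,44.0,6,VISIT 6,2023-03-23
FIX01,FIX01-0003,BILI,Bilirubin,8.9,umol/L,3.0,21.0,6,VISIT 6,2023-03-23
FIX01,FIX01-0003,CREAT,Creatinine,45.5,umol/L,49.0,90.0,6,VISIT 6,2023-03-23
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,30.1,U/L,7.0,44.0,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,BILI,Bilirubin,23.0,umol/L,3.0,21.0,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,CREAT,Creatinine,44.5,umol/L,49.0,90.0,1,VISIT 1,2023-03-01
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,11.0,U/L,7.0,44.0,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,BILI,Bilirubin,18.8,umol/L,3.0,21.0,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,CREAT,Creatinine,88.4,umol/L,49.0,90.0,2,VISIT 2,2023-03-15
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,44.9,U/L,7.0,44.0,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,BILI,Bilirubin,26.1,umol/L,3.0,21.0,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,CREAT,Creatinine,89.6,umol/L,49.0,90.0,3,VISIT 3,2023-03-28
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,35.1,U/L,7.0,44.0,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,BILI,Bilirubin,26.6,umol/L,3.0,21.0,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,CREAT,Creatinine,78.0,umol/L,49.0,90.0,4,VISIT 4,2023-04-12
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,20.7,U/L,7.0,44.0,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,BILI,Bilirubin,10.2,umol/L,3.0,21.0,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,CREAT,Creatinine,93.7,umol/L,49.0,90.0,5,VISIT 5,2023-04-26
FIX01,FIX01-0004,ALT,Alanine Aminotransferase,32.2,U/L,7.0,44.0,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,BILI,Bilirubin,17.0,umol/L,3.0,21.0,6,VISIT 6,2023-05-09
FIX01,FIX01-0004,CREAT,Creatinine,89.9,umol/L,49.0,90.0,6,VISIT 6,2023-05-09
FIX01,FIX01-0005,ALT,Alanine Aminotransferase,51.6,U/L,7.0,44.0,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,BILI,Bilirubin,16.1,umol/L,3.0,21.0,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,CREAT,Creatinine,103.3,umol/L,49.0,90.0,1,VISIT 1,2023-02-27
FIX01,FIX01-0005,ALT,Alanine Aminotransferase,20.3,U/L,7.0,44.0,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,BILI,Bilirubin,16.6,umol/L,3.0,21.0,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,CREAT,Creatinine,88.9,umol/L,49.0,90.0,2,VISIT 2,2023-03-12
FIX01,FIX01-0005,ALT,Alanine Aminotransferase,23.5,U/L,7.0,44.0,3,VISIT 3,2023-03-27
FIX01,FIX01-0005,BILI,Bilirubin,23.1,umol/L,3.0,21.0,3,VISIT 3,2023-03-27
FIX01,FIX01-0005,CREAT,Creatinine,85.9,umol/L,49.0,90.0,3,VISIT 3,2023-03-27
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,51.5,U/L,7.0,44.0,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,BILI,Bilirubin,18.0,umol/L,3.0,21.0,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,CREAT,Creatinine,91.1,umol/L,49.0,90.0,1,VISIT 1,2023-02-17
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,43.7,U/L,7.0,44.0,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,BILI,Bilirubin,21.9,umol/L,3.0,21.0,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,CREAT,Creatinine,69.5,umol/L,49.0,90.0,2,VISIT 2,2023-03-04
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,24.4,U/L,7.0,44.0,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,BILI,Bilirubin,26.1,umol/L,3.0,21.0,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,CREAT,Creatinine,83.7,umol/L,49.0,90.0,3,VISIT 3,2023-03-16
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,29.9,U/L,7.0,44.0,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,BILI,Bilirubin,26.2,umol/L,3.0,21.0,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,CREAT,Creatinine,96.6,umol/L,49.0,90.0,4,VISIT 4,2023-04-01
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,44.7,U/L,7.0,44.0,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,BILI,Bilirubin,15.4,umol/L,3.0,21.0,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,CREAT,Creatinine,61.5,umol/L,49.0,90.0,5,VISIT 5,2023-04-15
FIX01,FIX01-0006,ALT,Alanine Aminotransferase,25.7,U/L,7.0,44.0,6,VISIT 6,2023-04-28
FIX01,FIX01-0006,BILI,Bilirubin,16.3,umol/L,3.0,21.0,6,VISIT 6,2023-04-28
FIX01,FIX01-0006,CREAT,Creatinine,66.0,umol/L,49.0,90.0,6,VISIT 6,2023-04-28
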