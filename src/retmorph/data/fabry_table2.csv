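patient_id,family_id,sex,age,onset_age,alpha_gal,lyso_gb3,mssi,hypertension,visual_impairment,mri_age,arwmc,fazekas,epvs,mars,lacuna,svds,gca
1,F1,M,23,7,0.8,97.8,13,Yes,Yes,16,2,1,1,0,0,1,2
2,F1,F,50,18,26,9.37,7,No,No,43,14,3,2,NA,0,NA,6
3,F2,M,16,9,1.8,76.93,6,No,No,16,0,0,0,0,0,0,0
4,F2,F,54,7,2.07,5.2,9,No,No,57,0,0,0,NA,0,NA,0
5,F3,M,46,7,0.9,51.71,34,No,No,36,6,2,2,0,1,1,5
6,F3,F,49,7,5.88,2.99,18,Yes,No,39,6,2,0,NA,1,NA,6
7,F4,F,73,5,21.4,NA,28,No,No,62,14,3,1,NA,0,NA,13
8,F4,M,41,9,0.6,200,33,No,No,34,4,1,2,0,0,1,4
9,F5,M,23,9,0.24,81.23,19,No,No,21,8,2,3,0,0,2,14
10,F6,M,34,10,0.31,32.47,19,No,No,25,2,0,0,NA,0,NA,0
11,F6,F,40,7,2.54,3.08,11,No,No,30,2,1,0,NA,0,NA,0
12,F6,F,64,10,2.37,3.31,18,Yes,No,57,18,3,2,NA,3,NA,15
13,F7,M,35,7,0.1,NA,36,No,No,26,0,0,1,0,0,0,0
14,F7,M,16,6,1,NA,10,No,No,7,0,0,1,0,0,0,0
15,F8,F,37,5,16.4,NA,5,No,No,29,2,1,1,NA,0,NA,0
16,F8,M,60,8,0.8,NA,42,Yes,No,50,14,3,2,4,3,3,7
17,F9,M,30,9,0.7,55.34,23,Yes,Yes,24,4,1,0,0,0,1,2
18,F9,M,46,7,0.61,105.12,10,No,No,39,8,2,2,2,4,3,11
19,F10,M,35,10,0.3,89.18,20,No,No,27,4,1,2,4,2,3,0
20,F11,M,36,5,2.4,NA,33,No,No,26,2,1,1,NA,0,NA,0
21,F12,M,21,5,1.4,NA,20,No,No,15,2,1,1,0,0,1,NA
22,F13,M,39,7,0.23,81.14,38,No,No,37,2,1,3,2,1,3,8
23,F14,M,53,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
24,F14,F,28,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
25,F3,M,17,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
26,F5,M,51,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
27,F6,M,32,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
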