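param,summary_type,fd_center,fd_spread_low,fd_spread_high,ctrl_center,ctrl_spread_low,ctrl_spread_high,p_value
SDa,median_iqr,15.39,10.56,18.74,13.15,10.27,19.31,0.723
SDv,mean_sd,25.02,7.97,,25.08,7.09,,0.977
CRAE,mean_sd,138.45,26.16,,159,18.15,,0.001
CRVE,mean_sd,226.41,29.14,,240.51,21.76,,0.049
VLD,mean_sd,0.03,0.01,,0.04,0.005,,0.001
VAD,mean_sd,0.11,0.02,,0.13,0.01,,0.001
AVR,median_iqr,0.63,0.56,0.70,0.64,0.62,0.70,0.272
LDRa,median_iqr,12.71,7.45,23.11,8.81,4.90,14.71,0.172
LDRv,median_iqr,8.27,4.17,9.57,10.37,7.13,13.51,0.167
AAa,mean_sd,34.73,13.37,,32.14,11.14,,0.460
AAv,median_iqr,26.01,19.16,36.73,38.96,31.14,46.42,0.003
ARa,mean_sd,0.59,0.17,,0.45,0.13,,0.002
ARv,median_iqr,0.41,0.28,0.53,0.32,0.27,0.36,0.037
ODa,median_iqr,0.14,0.09,0.20,0.14,0.09,0.21,0.816
ODv,median_iqr,0.09,0.06,0.13,0.12,0.09,0.17,0.098
BAa,median_iqr,77.51,68.94,91.02,87.30,77.23,105.04,0.041
BAv,median_iqr,85.26,70.37,114.93,85.84,74.24,107.46,0.883
BCa,median_iqr,1.30,1.01,1.43,1.32,1.14,1.49,0.547
BCv,median_iqr,1.04,0.92,1.15,1.11,0.92,1.41,0.295
NFBa,median_iqr,3.00,1.00,4.00,3.00,3.00,4.00,0.052
NFBv,median_iqr,3.00,2.00,4.00,4.00,3.00,4.00,0.421
JEDa,median_iqr,-0.07,-0.44,0.46,-0.13,-0.35,0.07,0.509
JEDv,median_iqr,0.31,-0.02,0.57,0.21,-0.17,0.43,0.197
CTa,median_iqr,0.58,0.42,1.05,0.46,0.36,0.52,0.064
CTv,median_iqr,0.71,0.49,1.19,0.57,0.51,0.69,0.037
STa,median_iqr,1.09,1.08,1.12,1.08,1.07,1.10,0.059
STv,median_iqr,1.09,1.09,1.11,1.08,1.08,1.10,0.037
FrD,median_iqr,1.54,1.50,1.55,1.58,1.56,1.58,0.001
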