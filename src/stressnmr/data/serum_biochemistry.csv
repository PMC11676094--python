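analyte,unit,control_mean,control_sd,stressed_mean,stressed_sd,significance
TP,g/L,43.65,7.36,43.73,2.22,
Alb,g/L,25.20,3.43,24.21,0.74,
Glo,g/L,18.45,4.15,19.51,1.52,
Alb/Glo,ratio,1.39,0.17,1.25,0.06,
Tbil,umol/L,2.45,1.04,1.97,0.25,
Dbil,umol/L,1.45,1.14,0.69,0.13,
Ibil,umol/L,1.00,0.20,1.28,0.15,*
ALT,U/L,39.50,14.60,36.40,9.60,
AST,U/L,134.50,43.02,145.28,24.55,
AST/ALT,ratio,3.57,1.06,4.07,0.49,
GGT,U/L,0.10,0.04,0.18,0.26,
ALP,U/L,231.33,59.86,252.18,54.72,
TG,mmol/L,1.07,0.78,0.93,0.48,
TC,mmol/L,1.86,0.34,1.79,0.11,
HDL,mmol/L,0.51,0.09,0.53,0.05,
LDL,mmol/L,0.15,0.05,0.15,0.02,
Glc,mmol/L,4.93,0.58,3.37,0.27,**
LDH,U/L,1070.77,410.95,1395.87,183.29,
BUN,mmol/L,3.82,1.56,4.48,0.84,
Cn,umol/L,39.33,12.97,44.13,2.80,
BUN/Cn,ratio,0.10,0.02,0.10,0.01,
UA,umol/L,164.67,78.32,104.58,26.78,
TBA,umol/L,33.60,19.64,52.73,47.84,
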