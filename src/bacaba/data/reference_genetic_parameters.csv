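trait,unit,GMS,RMS,mean,CVe_pct,CVg_pct,cvg_over_cve,h2mp_pct
FL,mm,13.45,1.20,16.40,6.67,5.70,0.85,91.09
WF,mm,15.16,0.99,14.76,6.76,6.82,1.01,93.45
FM,g,2.60,0.08,2.54,11.16,16.72,1.50,96.82
PM,g,0.40,0.02,0.86,15.09,19.27,1.28,95.81
SM,g,1.30,0.06,1.68,14.23,17.75,1.25,95.61
PT,mm,0.25,0.04,1.65,11.56,7.47,0.65,85.38
AT,mm,3.06,0.19,5.53,7.86,8.19,0.99,93.82
PY,%,164.91,18.99,34.06,12.80,9.48,0.74,88.48
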