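genotype,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15
1,0.0,21.48,3.61,12.06,7.27,5.47,3.85,16.34,8.86,6.61,3.53,5.54,7.16,19.31,3.83
2,21.48,0.0,21.76,21.1,43.82,18.97,29.37,48.1,9.93,10.51,13.02,13.36,14.53,0.95,21.71
3,3.61,21.76,0.0,7.86,5.01,4.52,1.39,19.74,4.05,4.0,2.24,3.8,7.92,20.33,0.07
4,12.06,21.1,7.86,0.0,16.33,9.03,11.04,13.32,7.19,5.93,5.1,3.51,5.72,18.35,7.17
5,7.27,43.82,5.01,16.33,0.0,9.78,3.87,14.84,17.34,16.77,11.73,14.74,19.88,42.64,5.62
6,5.47,18.97,4.52,9.03,9.78,0.0,4.42,19.46,8.3,7.42,3.78,6.47,13.13,18.83,4.94
7,3.85,29.37,1.39,11.04,3.87,4.42,0.0,20.25,8.76,7.61,3.75,6.53,11.76,26.93,1.43
8,16.34,48.1,19.74,13.32,14.84,19.46,20.25,0.0,30.12,26.77,20.4,20.73,19.16,45.14,19.84
9,8.86,9.93,4.05,7.19,17.34,8.3,8.76,30.12,0.0,0.64,2.61,2.05,5.52,8.98,3.75
10,6.61,10.51,4.0,5.93,16.77,7.42,7.61,26.77,0.64,0.0,1.23,0.59,3.29,8.41,3.52
11,3.53,13.02,2.24,5.1,11.73,3.78,3.75,20.4,2.61,1.23,0.0,0.7,3.68,11.5,1.9
12,5.54,13.36,3.8,3.51,14.74,6.47,6.53,20.73,2.05,0.59,0.7,0.0,2.16,10.49,3.21
13,7.16,14.53,7.92,5.72,19.88,13.13,11.76,19.16,5.52,3.29,3.68,2.16,0.0,10.4,7.09
14,19.31,0.95,20.33,18.35,42.64,18.83,26.93,45.14,8.98,8.41,11.5,10.49,10.4,0.0,19.85
15,3.83,21.71,0.07,7.17,5.62,4.94,1.43,19.84,3.75,3.52,1.9,3.21,7.09,19.85,0.0
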