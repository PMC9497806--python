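series,allREC,dREC,allDET,dDET,allLMAX,dLMAX,allENT,dENT,allLAM,dLAM,allTT,dTT
LKNEx_J,8.61,8.08,99.59,99.60,1018,1019,5.75,5.83,99.74,99.77,16.54,19.95
LKNEy_J,43.34,41.2,99.8,99.85,2212,2243,6.9,7.1,99.9,99.93,54.08,65.31
LKNEz_J,90.41,82.46,99.93,99.96,3935,3972,7.54,8.17,99.97,99.98,163.39,223.12
LKNEx_C,1.6,1.62,99.6,99.61,1246,1305,5.69,5.75,98.33,99.65,9.7,15.36
LKNEy_C,16.3,20.1,99.72,99.86,2109,2210,6.46,7.05,99.87,99.94,43.45,77.38
LKNEz_C,10.5,18.51,99.81,99.92,2425,2514,6.44,7.23,99.9,99.97,36.36,67.22
CoMx_J,2,2.87,99.73,99.76,915,945,6.29,6.30,99.74,99.85,16.2,20.82
CoMy_J,11.97,18.16,99.91,99.93,3939,3967,7.23,7.37,99.95,99.97,37.3,46.92
CoMz_J,86.35,86.52,99.98,99.98,3939,3963,8.23,8.26,99.99,99.99,261.59,262
CoMx_C,1.12,1.63,99.65,99.74,1536,1600,6.25,6.32,99.64,99.85,12.36,20.96
CoMy_C,9.84,12.74,99.87,99.93,3927,3987,6.83,7.14,99.95,99.98,38.04,55.04
CoMz_C,32.59,42.18,99.93,99.94,3927,3954,7.15,7.32,99.97,99.98,76.2,89.77
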