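run,mean,sd,sn,taguchi_fitted
L1,3.81,0.23,11.59,3.70
L2,3.12,0.10,9.86,3.12
L3,2.32,0.01,7.30,2.43
L4,5.37,0.07,14.60,5.53
L5,4.94,0.05,13.88,4.94
L6,4.41,0.10,12.88,4.26
L7,7.23,0.09,17.18,7.19
L8,6.60,0.17,16.39,6.61
L9,5.88,0.09,15.39,5.92
L10,5.43,0.11,14.69,5.50
L11,5.84,0.08,15.33,5.83
L12,6.19,0.05,15.84,6.14
L13,4.74,0.06,13.51,4.63
L14,4.91,0.07,13.81,4.96
L15,5.22,0.04,14.35,5.27
L16,4.83,0.06,13.67,4.87
L17,5.24,0.05,14.39,5.20
L18,5.51,0.09,14.82,5.51
L19,5.52,0.05,14.84,5.42
L20,5.54,0.06,14.86,5.67
L21,6.18,0.12,15.81,6.15
L22,5.53,0.14,14.85,5.56
L23,5.80,0.12,15.27,5.81
L24,6.32,0.10,16.01,6.28
L25,4.72,0.08,13.48,4.81
L26,5.21,0.10,14.34,5.07
L27,5.48,0.15,14.76,5.54
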