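batch_id,UR,AD,CGA,CFA,CCA,LGR,LG,IC50
S1,3.31,3.40,10.32,14.78,58.30,74.63,5.63,4.01
S2,2.73,8.31,7.85,9.57,60.23,75.30,5.72,4.24
S3,2.73,6.48,6.51,15.07,62.37,83.23,4.56,4.52
S4,2.45,5.27,7.07,15.84,64.69,88.41,5.34,4.94
S5,2.55,6.16,6.13,14.84,62.31,82.88,4.59,4.11
S6,2.17,5.65,6.49,15.94,60.82,81.69,4.75,4.12
S7,2.18,2.30,7.93,19.44,76.98,86.10,6.50,4.40
S8,3.53,3.92,8.73,22.88,90.60,89.30,6.51,4.61
S9,2.98,1.76,7.81,17.09,71.73,71.42,4.72,4.64
S10,3.91,9.49,9.22,16.92,61.29,81.36,4.34,4.34
S11,3.19,2.20,8.34,18.62,81.98,86.66,6.74,4.28
S12,3.05,2.48,8.03,18.00,74.36,79.01,5.93,4.70
S13,3.16,3.71,8.33,18.21,74.46,94.52,8.17,4.27
S14,2.91,3.95,8.79,15.36,66.27,108.74,15.90,4.26
S15,3.63,4.67,8.04,21.51,77.63,110.90,8.83,4.40
S16,3.86,5.63,8.09,23.21,78.81,109.19,9.22,3.96
S17,3.91,3.46,7.98,22.55,82.42,116.00,8.95,4.45
S18,3.32,4.59,8.18,19.91,89.29,95.93,7.17,3.90
S19,3.80,4.94,7.57,21.94,75.69,104.23,8.21,3.81
S20,2.38,5.56,6.51,15.44,62.77,82.63,4.48,4.57
S21,2.22,0.06,1.55,7.44,40.97,145.19,14.64,5.48
S22,3.58,5.28,10.07,18.41,65.67,135.37,14.99,3.48
S23,2.28,ND,2.80,3.28,46.06,150.95,15.22,5.55
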