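batch_id,channel,sm,pm,alpha,grade
S1,260,0.89,89.5,0.07,3
S2,260,0.98,88.3,0.07,3
S3,260,0.96,91.1,0.01,2
S4,260,0.96,95.6,0.02,1
S5,260,0.97,92.2,0.01,2
S6,260,0.97,91.0,0.03,2
S7,260,0.98,94.0,0.03,2
S8,260,0.89,102.6,0.06,3
S9,260,0.97,82.9,0.07,3
S10,260,0.9,94.9,0.1,3
S11,260,0.98,94.8,0.05,2
S12,260,0.97,89.0,0.06,3
S13,260,0.98,98.5,0.01,1
S14,260,0.97,105.1,0.06,2
S15,260,0.98,111.1,0.01,3
S16,260,0.98,109.5,0.0,2
S17,260,0.97,114.1,0.03,3
S18,260,0.98,103.2,0.03,1
S19,260,0.98,107.2,0.0,2
S20,260,0.97,92.4,0.01,2
S21,260,0.87,104.6,0.25,5
S22,260,0.96,120.0,0.09,3
S23,260,0.89,110.2,0.24,5
RFP,260,1.0,100.0,0.0,1
S1,265,0.91,91.1,0.1,3
S2,265,0.96,87.0,0.07,3
S3,265,0.97,87.0,0.07,3
S4,265,0.96,92.4,0.02,2
S5,265,0.97,96.7,0.01,1
S6,265,0.97,91.1,0.03,2
S7,265,0.97,89.6,0.02,3
S8,265,0.97,102.9,0.05,2
S9,265,0.96,83.3,0.05,3
S10,265,0.97,95.1,0.12,3
S11,265,0.97,94.4,0.03,2
S12,265,0.97,88.3,0.04,3
S13,265,0.98,97.8,0.01,1
S14,265,0.97,104.9,0.05,1
S15,265,0.97,111.6,0.02,3
S16,265,0.97,109.1,0.02,2
S17,265,0.98,114.8,0.03,3
S18,265,0.97,103.5,0.03,1
S19,265,0.97,106.4,0.0,2
S20,265,0.96,91.6,0.01,2
S21,265,0.86,107.9,0.24,5
S22,265,0.96,116.8,0.09,3
S23,265,0.86,113.5,0.24,5
RFP,265,1.0,100.0,0.0,1
S1,330,0.97,94.6,0.01,2
S2,330,0.97,94.4,0.03,2
S3,330,0.97,98.3,0.05,2
S4,330,0.98,103.0,0.05,1
S5,330,0.98,98.9,0.05,1
S6,330,0.99,97.6,0.05,1
S7,330,0.98,99.1,0.01,1
S8,330,0.98,110.9,0.02,3
S9,330,0.97,91.3,0.01,2
S10,330,0.99,98.4,0.01,1
S11,330,0.98,100.0,0.01,1
S12,330,0.99,95.3,0.0,1
S13,330,0.98,99.1,0.02,1
S14,330,0.98,107.0,0.02,2
S15,330,0.99,105.4,0.03,2
S16,330,0.99,105.8,0.03,2
S17,330,0.99,109.6,0.02,2
S18,330,0.99,109.5,0.01,2
S19,330,0.99,101.9,0.03,1
S20,330,0.98,98.7,0.05,1
S21,330,0.87,72.6,0.05,5
S22,330,0.97,110.7,0.0,3
S23,330,0.88,74.7,0.06,5
RFP,330,1.0,100.0,0.0,1
S1,335,0.97,94.4,0.01,2
S2,335,0.96,93.9,0.02,2
S3,335,0.97,98.0,0.05,2
S4,335,0.98,102.6,0.05,1
S5,335,0.97,97.6,0.05,1
S6,335,0.98,96.4,0.05,1
S7,335,0.98,97.7,0.0,1
S8,335,0.98,111.5,0.02,3
S9,335,0.96,90.5,0.01,2
S10,335,0.97,96.9,0.01,1
S11,335,0.98,100.2,0.0,1
S12,335,0.98,94.3,0.01,2
S13,335,0.99,99.2,0.02,1
S14,335,0.96,107.5,0.02,2
S15,335,0.99,105.6,0.02,2
S16,335,0.99,106.3,0.03,2
S17,335,0.98,109.2,0.02,2
S18,335,0.99,109.7,0.01,2
S19,335,0.99,101.8,0.03,1
S20,335,0.96,97.4,0.05,2
S21,335,0.9,75.5,0.06,4
S22,335,0.97,110.9,0.0,3
S23,335,0.89,78.1,0.07,4
RFP,335,1.0,100.0,0.0,1
S1,350,0.97,89.5,0.03,3
S2,350,0.97,90.1,0.02,2
S3,350,0.98,93.2,0.02,2
S4,350,0.94,99.2,0.01,2
S5,350,0.97,93.9,0.01,2
S6,350,0.97,93.2,0.02,2
S7,350,0.98,97.0,0.01,1
S8,350,0.97,105.0,0.01,2
S9,350,0.98,86.1,0.01,3
S10,350,0.98,93.3,0.02,2
S11,350,0.97,96.3,0.01,1
S12,350,0.98,92.2,0.02,2
S13,350,0.99,99.3,0.02,1
S14,350,0.95,109.2,0.02,2
S15,350,0.99,108.8,0.0,2
S16,350,0.98,107.5,0.0,2
S17,350,0.98,112.0,0.01,3
S18,350,0.96,105.7,0.01,2
S19,350,0.97,104.2,0.01,1
S20,350,0.97,94.6,0.02,2
S21,350,0.89,93.5,0.17,4
S22,350,0.95,114.5,0.02,3
S23,350,0.88,97.0,0.18,4
RFP,350,1.0,100.0,0.0,1
S1,integrated,0.94,91.8,0.06,2
S2,integrated,0.97,90.8,0.05,2
S3,integrated,0.97,93.6,0.05,2
S4,integrated,0.96,98.6,0.03,1
S5,integrated,0.97,95.9,0.03,1
S6,integrated,0.97,93.9,0.03,2
S7,integrated,0.98,95.5,0.02,1
S8,integrated,0.96,106.7,0.04,2
S9,integrated,0.97,86.9,0.04,3
S10,integrated,0.96,95.7,0.07,2
S11,integrated,0.98,97.2,0.03,1
S12,integrated,0.97,91.9,0.03,2
S13,integrated,0.98,98.8,0.01,1
S14,integrated,0.97,106.8,0.04,2
S15,integrated,0.98,108.5,0.02,2
S16,integrated,0.98,107.7,0.02,2
S17,integrated,0.98,112.0,0.02,3
S18,integrated,0.98,106.4,0.02,2
S19,integrated,0.98,104.3,0.02,1
S20,integrated,0.97,95.0,0.03,2
S21,integrated,0.88,92.0,0.17,4
S22,integrated,0.96,114.6,0.06,3
S23,integrated,0.88,96.0,0.17,4
RFP,integrated,1.0,100.0,0.0,1
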