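case,device,artery,wss_pa,osi,lwssa_cm2,hosia_cm2,dp_mmhg
Case 01,PAPS I,LPA,4.88,0.08,0.08,0.48,1.0
Case 01,PAPS II,RPA,4.38,0.13,0.07,1.26,0.4
Case 02,PAPS I,LPA,3.15,0.04,0.22,0.18,2.2
Case 02,PAPS II,RPA,2.78,0.24,0.06,1.77,1.6
Case 03,PAPS I,LPA,3.59,0.07,0.08,0.38,0.7
Case 03,PAPS II,RPA,3.65,0.05,0.25,0.18,-0.8
Case 04,PAPS I,LPA,2.37,0.25,0.10,1.55,-0.5
Case 04,PAPS II,RPA,2.08,0.08,0.42,0.43,-0.5
Case 05,PAPS I,LPA,3.70,0.12,0.10,0.62,1.0
Case 05,PAPS II,RPA,3.80,0.10,0.25,0.43,0.2
Case 06,PAPS I,LPA,2.98,0.05,0.18,0.26,2.9
Case 06,PAPS II,RPA,2.43,0.08,0.33,0.50,0.1
Case 07,PAPS I,LPA,3.89,0.09,0.04,0.70,0.4
Case 07,PAPS II,RPA,2.19,0.11,0.25,0.49,0.4
Case 08,PAPS I,LPA,2.25,0.11,0.34,0.67,2.8
Case 08,PAPS II,RPA,2.27,0.04,0.27,0.17,1.4
Case 09,PAPS I,LPA,1.64,0.21,0.19,1.19,-0.3
Case 09,PAPS II,RPA,4.16,0.12,0.21,1.11,1.1
Case 10,PAPS I,LPA,2.89,0.04,0.32,0.19,0.3
Case 10,PAPS II,RPA,2.26,0.13,0.35,0.93,-0.7
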