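case,wss_pre_pa,wss_post_pa,osi_pre,osi_post,lwssa_pre_cm2,lwssa_post_cm2,hosia_pre_cm2,hosia_post_cm2
Case 01,2.71,2.96,0.07,0.08,0.02,0.18,14.46,15.08
Case 02,2.63,2.70,0.09,0.09,0.42,1.01,21.60,23.40
Case 03,1.86,1.96,0.11,0.11,7.92,8.52,32.40,31.29
Case 04,2.22,2.30,0.09,0.10,0.92,1.64,23.63,22.59
Case 05,3.37,3.48,0.09,0.09,0.24,1.04,16.48,17.92
Case 06,2.14,2.23,0.07,0.07,2.99,3.37,15.21,16.04
Case 07,1.89,2.00,0.07,0.07,1.06,1.39,12.38,11.13
Case 08,2.22,2.23,0.08,0.08,6.55,7.07,17.95,18.23
Case 09,2.56,2.70,0.06,0.06,1.51,1.69,12.28,11.36
Case 10,1.92,1.98,0.06,0.07,2.94,3.46,14.36,16.84
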