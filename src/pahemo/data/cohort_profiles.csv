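case,weight_kg,hr_bpm,co_lpm,qmax_mls,pa_area_cm2
Case 01,62,99,4.7,245,135
Case 02,59,101,4.6,224,156
Case 03,58,102,4.6,216,169
Case 04,72,95,5.1,220,136
Case 05,55,104,4.4,238,138
Case 06,65,104,4.4,241,164
Case 07,65,98,4.8,176,150
Case 08,65,98,4.9,238,149
Case 09,65,98,4.8,173,149
Case 10,65,98,4.8,189,171
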