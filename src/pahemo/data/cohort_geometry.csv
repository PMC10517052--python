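case,mpa_l_mm,mpa_d_mm,rpa_l_mm,rpa_d_mm,lpa_l_mm,lpa_d_mm,alpha_deg
Case 01,59.4,21.4,115.5,13.2,100.9,12.1,81
Case 02,78.0,21.3,115.1,13.1,105.4,12.7,73
Case 03,82.7,28.0,105.9,15.5,91.6,14.9,85
Case 04,52.0,23.3,81.1,15.3,105.9,17.1,91
Case 05,56.2,22.2,122.9,13.0,103.1,12.6,84
Case 06,76.6,24.3,129.6,12.1,102.4,12.1,86
Case 07,56.9,25.6,106.0,17.5,114.4,12.5,79
Case 08,69.6,26.0,113.8,16.7,103.2,12.8,75
Case 09,58.1,22.5,130.0,17.5,117.9,15.2,68
Case 10,75.8,24.0,121.2,14.6,73.9,13.5,82
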