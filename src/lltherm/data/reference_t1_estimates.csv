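sample,measured_temp_c,measured_temp_err,t1_calibrated_ms,t1_calibrated_err,t1_constant_na12_ms,t1_constant_na12_err,t1_variable_ms,t1_variable_err
S1,24.3,0.2,51,5,39,5,41,4
S2,24.3,0.2,99,5,85,5,87,4
S3,24.3,0.2,138,8,120,7,126,7
S4,24.3,0.2,200,10,171,9,177,11
S5,24.3,0.2,235,13,197,9,203,8
S6,24.2,0.1,288,13,220,18,243,15
S7,24.2,0.1,341,17,286,28,306,34
S8,24.2,0.1,385,20,314,27,338,27
S9,24.2,0.1,470,39,358,29,399,33
S10,24.2,0.1,524,47,387,23,412,21
S11,24.2,0.2,596,49,382,65,468,73
S12,24.2,0.2,682,58,493,97,565,78
S13,24.2,0.2,819,92,598,123,713,198
S14,24.2,0.2,1005,145,653,108,826,160
S15,24.2,0.2,1759,261,908,176,1516,500
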