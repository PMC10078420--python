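sample,measured_temp_c,measured_temp_err,t1_ms,t1_sd_ms
S1,24.3,0.2,41,4
S1,29.0,0.2,44,5
S1,32.6,0.3,48,4
S1,37.4,0.4,53,5
S1,40.1,0.5,54,6
S1,41.7,0.6,60,7
S2,24.3,0.2,87,4
S2,29.0,0.2,93,7
S2,32.6,0.3,103,7
S2,37.4,0.4,113,8
S2,40.1,0.5,118,6
S2,41.7,0.6,124,8
S3,24.3,0.2,126,7
S3,29.0,0.2,134,10
S3,32.6,0.3,151,11
S3,37.4,0.4,158,10
S3,40.1,0.5,170,10
S3,41.7,0.6,182,10
S4,24.3,0.2,177,11
S4,29.0,0.2,188,11
S4,32.6,0.3,208,12
S4,37.4,0.4,231,16
S4,40.1,0.5,244,14
S4,41.7,0.6,266,23
S5,24.3,0.2,203,8
S5,29.0,0.2,219,9
S5,32.6,0.3,243,10
S5,37.4,0.4,266,10
S5,40.1,0.5,276,13
S5,41.7,0.6,297,20
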