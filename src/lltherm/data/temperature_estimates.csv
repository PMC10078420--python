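sample,measured_temp_c,measured_temp_err,estimated_temp_c,estimated_temp_sd_c
S1,29.0,0.2,27.4,3.8
S1,32.6,0.3,31.3,3.0
S1,37.4,0.4,35.4,3.9
S1,40.1,0.5,37.1,6.7
S1,41.7,0.6,41.5,4.5
S2,29.0,0.2,26.8,2.2
S2,32.6,0.3,31.1,2.3
S2,37.4,0.4,35.3,2.6
S2,40.1,0.5,37.8,2.8
S2,41.7,0.6,40.2,2.5
S3,29.0,0.2,27.0,2.1
S3,32.6,0.3,32.1,2.5
S3,37.4,0.4,34.0,2.2
S3,40.1,0.5,37.9,4.0
S3,41.7,0.6,41.3,3.7
S4,29.0,0.2,26.7,2.1
S4,32.6,0.3,31.0,2.4
S4,37.4,0.4,35.8,2.4
S4,40.1,0.5,38.7,2.8
S4,41.7,0.6,43.3,4.2
S5,29.0,0.2,27.2,1.6
S5,32.6,0.3,31.7,1.9
S5,37.4,0.4,36.0,2.3
S5,40.1,0.5,37.9,2.7
S5,41.7,0.6,41.7,3.4
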