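sample,mncl2_um,slope_ms_per_c,slope_err,intercept_ms,intercept_err,r2
S1,1350,1.25,0.08,21,3,0.95
S2,650,2.55,0.07,37,3,0.99
S3,450,3.7,0.1,48,5,0.99
S4,300,5.2,0.2,74,6,0.99
S5,250,6.4,0.2,80,8,0.99
S6,200,7.5,0.2,107,8,0.99
S7,160,9.5,0.3,111,10,0.99
S8,150,10.5,0.3,131,13,0.99
S9,120,14.4,0.6,122,24,0.98
S10,100,14.1,0.6,183,24,0.98
S11,80,17.0,0.8,185,32,0.97
S12,70,20.1,0.8,195,30,0.98
S13,60,23,1,268,39,0.98
S14,40,30,2,272,68,0.96
S15,10,49,3,574,102,0.96
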