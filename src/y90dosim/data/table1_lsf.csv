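patient_id,lsf_wb_st,lsf_spect_acsc,lsf_wb_sc,lsf_spect_noacsc
1,0.186,0.110,0.162,0.166
2,0.066,0.042,0.036,0.054
3,0.032,0.012,0.010,0.019
4,0.049,0.027,0.010,0.044
5,0.078,0.043,0.036,0.032
6,0.075,0.025,0.015,0.036
7,0.094,0.055,0.070,0.071
8,0.143,0.044,0.075,0.073
9,0.200,0.098,0.160,0.116
10,0.077,0.034,0.045,0.050
11,0.131,0.070,0.076,0.090
12,0.150,0.088,0.110,0.105
13,0.043,0.015,0.015,0.029
14,0.077,0.022,0.026,0.025
15,0.072,0.031,0.041,0.050
16,0.098,0.060,0.061,0.075
17,0.180,0.110,0.150,0.160
18,0.085,0.061,0.050,0.078
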