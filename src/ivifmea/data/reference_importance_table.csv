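error_code,score_k0,rank_k0,score_k0.25,rank_k0.25,score_k0.5,rank_k0.5,score_k0.75,rank_k0.75,score_k1,rank_k1
L18,0.559,15,0.591,15,0.623,15,0.655,15,0.687,15
L17,0.567,14,0.6,14,0.632,14,0.665,14,0.698,14
L16,0.57,12,0.603,12,0.636,12,0.669,12,0.702,12
L05,0.543,18,0.575,18,0.607,18,0.639,18,0.67,18
L01,0.555,16,0.587,16,0.62,16,0.652,16,0.684,16
I1g,0.576,9,0.61,9,0.644,9,0.678,9,0.711,9
I1a,0.569,13,0.601,13,0.634,13,0.667,13,0.7,13
I0a,0.546,17,0.578,17,0.61,17,0.641,17,0.673,17
I2b,0.585,7,0.619,7,0.654,7,0.688,7,0.723,7
I3c,0.573,11,0.606,11,0.64,11,0.673,11,0.706,11
di,0.603,3,0.639,3,0.674,3,0.71,3,0.745,3
kd,0.594,5,0.628,5,0.663,5,0.698,5,0.733,5
gd,0.576,8,0.61,8,0.644,8,0.678,8,0.712,8
tr,0.588,6,0.622,6,0.657,6,0.692,6,0.726,6
ts,0.573,10,0.607,10,0.64,10,0.674,10,0.707,10
HRHc,0.621,1,0.658,1,0.695,1,0.732,1,0.769,1
TKHg,0.598,4,0.633,4,0.668,4,0.703,4,0.738,4
TKHa,0.618,2,0.655,2,0.693,2,0.73,2,0.767,2
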