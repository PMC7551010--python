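error_code,rpn_mu_lo,rpn_mu_hi,rpn_nu_lo,rpn_nu_hi,ideal_mu_lo,ideal_mu_hi,ideal_nu_lo,ideal_nu_hi,score,rank
L18,0.532,0.657,0.179,0.343,0,0.446,0.323,0.554,0.638,2
L17,0.538,0.663,0.172,0.337,0,0.451,0.318,0.549,0.635,1
L16,0.513,0.642,0.193,0.358,0,0.453,0.315,0.547,0.662,5
L05,0.516,0.649,0.189,0.351,0,0.441,0.331,0.559,0.644,4
L01,0.525,0.658,0.181,0.342,0,0.447,0.325,0.553,0.64,3
I1g,0.486,0.62,0.213,0.38,0,0.457,0.31,0.543,0.691,11
I1a,0.482,0.614,0.221,0.386,0,0.452,0.317,0.548,0.693,14
I0a,0.462,0.601,0.237,0.399,0,0.443,0.331,0.557,0.701,15
I2b,0.492,0.627,0.206,0.373,0,0.461,0.304,0.539,0.689,10
I3c,0.484,0.618,0.217,0.382,0,0.455,0.313,0.545,0.692,13
di,0.505,0.639,0.193,0.361,0,0.47,0.292,0.53,0.684,8
kd,0.498,0.632,0.201,0.368,0,0.465,0.299,0.535,0.686,9
gd,0.486,0.62,0.213,0.38,0,0.456,0.31,0.544,0.692,12
tr,0.455,0.597,0.204,0.403,0,0.462,0.302,0.538,0.719,17
ts,0.447,0.587,0.216,0.413,0,0.455,0.312,0.545,0.723,18
HRHc,0.517,0.651,0.179,0.349,0,0.479,0.28,0.521,0.679,6
TKHg,0.462,0.604,0.198,0.396,0,0.468,0.297,0.532,0.716,16
TKHa,0.513,0.65,0.179,0.35,0,0.479,0.28,0.521,0.68,7
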