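error_code,index_rank,reported_count_rank
L18,2,1
L17,1,2
L16,5,5
L05,4,4
L01,3,3
I1g,11,7
I1a,14,9
I0a,15,12
I2b,10,10
I3c,13,14
di,8,6
kd,9,11
gd,12,13
tr,17,17
ts,18,18
HRHc,6,8
TKHg,16,16
TKHa,7,15
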