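error_code,term
L18,High
L17,High
L16,Medium High
L05,High
L01,High
I1g,Medium
I1a,Medium
I0a,Medium
I2b,Medium
I3c,Medium
di,Medium
kd,Medium
gd,Medium
tr,Medium-Low
ts,Medium-Low
HRHc,Medium
TKHg,Medium-Low
TKHa,Medium
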