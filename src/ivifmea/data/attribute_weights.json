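{
  "severity": 0.387,
  "preventability": 0.334,
  "occurrence": 0.279
}
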