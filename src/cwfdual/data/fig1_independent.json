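{
  "L": 2,
  "M": [2, 2],
  "h": [0.0, 0.0, 0.0, 0.0],
  "J": {
    "(1,2)": [[0.0, 0.0], [0.0, 0.0]]
  },
  "pim_u": [[0.8, 0.8], [0.8, 0.8]]
}
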