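{
 "metabolites": ["M1", "M2"],
 "reactions": ["v1", "v2", "v3", "v4", "v5"],
 "S": [
  [1, -1, -1, -1, 0],
  [0, 1, 1, 1, -1]
 ],
 "lb": [-1, -10000, 0, -2, 0],
 "ub": [1, -2, 2, 10000, 10000]
}
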