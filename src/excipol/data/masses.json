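{
  "monomers": {
    "Morph": 141.17,
    "Nipam": 113.16,
    "Dodecyl": 239.4
  },
  "end_groups": {
    "CPDT": 345.6,
    "AIBN": 68.1,
    "V70": 140.2,
    "VA044": 147.7,
    "ACVA": 126.1,
    "none": 0.0
  }
}
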