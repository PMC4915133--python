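{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [8, 8]}
  ],
  "expected_pairs": [["ARTS", "XIAP-BIR3"]],
  "construct_tags": ["part-whole"]
}
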