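{
  "mentions": [
    {"tokens": [1, 3]},
    {"tokens": [10, 10]}
  ],
  "expected_pairs": [["Histone deacetylase 1", "Sp1"]],
  "construct_tags": ["null-argument"]
}
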