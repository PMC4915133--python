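{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [10, 10]}
  ],
  "expected_pairs": [["Shc", "GRB2"]],
  "construct_tags": ["full-relative-clause", "part-whole"]
}
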