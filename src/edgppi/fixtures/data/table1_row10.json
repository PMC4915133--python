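{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [8, 11]}
  ],
  "expected_pairs": [["TPO", "myeloproliferative leukemia virus receptor"]],
  "construct_tags": ["appositive", "coordination"]
}
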