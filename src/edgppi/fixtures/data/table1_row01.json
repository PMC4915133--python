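{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [5, 6]}
  ],
  "expected_pairs": [["HFE", "transferrin receptor"]],
  "construct_tags": ["active"]
}
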