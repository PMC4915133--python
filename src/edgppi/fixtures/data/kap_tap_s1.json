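{
  "mentions": [
    {"tokens": [1, 2]},
    {"tokens": [6, 6]},
    {"tokens": [11, 11]}
  ],
  "expected_pairs": [["Kap β2B", "TAP"]],
  "construct_tags": ["passive"]
}
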