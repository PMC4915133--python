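{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [12, 12]}
  ],
  "expected_pairs": [["CD5", "CD72"]],
  "construct_tags": ["is-a"]
}
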