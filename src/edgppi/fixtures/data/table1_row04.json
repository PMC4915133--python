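{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [5, 5]}
  ],
  "expected_pairs": [["Raf-1", "Ras"]],
  "construct_tags": ["adjective"]
}
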