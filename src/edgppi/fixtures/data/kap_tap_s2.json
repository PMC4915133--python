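{
  "mentions": [
    {"tokens": [8, 9]},
    {"tokens": [20, 20]},
    {"tokens": [22, 23]},
    {"tokens": [36, 36]}
  ],
  "expected_pairs": [],
  "construct_tags": ["trigger-cooccurrence"]
}
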