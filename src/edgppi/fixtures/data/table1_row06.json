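{
  "mentions": [
    {"tokens": [3, 3]},
    {"tokens": [6, 6]},
    {"tokens": [15, 15]}
  ],
  "expected_pairs": [["ERK2", "PEA-15"]],
  "construct_tags": ["reduced-relative-clause"]
}
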