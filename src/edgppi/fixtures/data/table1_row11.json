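{
  "mentions": [
    {"tokens": [5, 5]},
    {"tokens": [12, 12]}
  ],
  "expected_pairs": [["RPA70N", "RAD9"]],
  "construct_tags": ["member-collection", "part-whole"]
}
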