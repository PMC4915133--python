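{
  "mentions": [
    {"tokens": [3, 5]},
    {"tokens": [7, 7]}
  ],
  "expected_pairs": [["G beta gamma", "Raf"]],
  "construct_tags": ["nominalization"]
}
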