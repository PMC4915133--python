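{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [6, 9]}
  ],
  "expected_pairs": [["p53", "xeroderma pigmentosum DDB2 gene"]],
  "construct_tags": ["coordination"]
}
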