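{
  "mentions": [
    {"tokens": [1, 1]},
    {"tokens": [8, 8]},
    {"tokens": [10, 17]},
    {"tokens": [20, 21]},
    {"tokens": [23, 23]}
  ],
  "expected_pairs": [["TR6", "LIGHT"], ["TR6", "Fas ligand"]],
  "construct_tags": ["combination", "coordination", "appositive", "coreference"]
}
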