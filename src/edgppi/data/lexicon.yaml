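# Default trigger lexicon.  Only base forms (lemmas) are listed; gerunds and
# -ion nominalizations are recognized automatically.  Users curating against
# a fuller trigger inventory can extend any of these sets.
ppi_verbs:
  - bind
  - interact
  - crosslink
  - associate
  - activate
ptm_verbs:
  - acetylate
  - methylate
  - phosphorylate
noun_triggers:
  - complex
  - dimer
  - heterodimer
  - homodimer
indirect_triggers:
  - block
  - mediate
process_triggers:
  - activity
technique_keywords:
  - 2-hybrid
  - bifc
  - cosedimentation
  - itc
  - pulldown
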