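# edgppi

Rule-based detection of protein–protein interaction (PPI) passages in
full-text biomedical articles, built on **extended dependency graphs
(EDGs)**, with BioC XML input/output so the annotations drop straight into a
biocuration pipeline.

Full text states the same interaction in many surface forms — active and
passive clauses, nominalizations ("the interaction of X with Y"),
adjectival participles ("Raf-1-binding proteins"), relative clauses,
coordination, apposition, part–whole phrasing ("binds to a domain in
XIAP-BIR3"). Pattern-based extractors usually need one rule per variation.
This package instead normalizes the sentence representation first, so that a
handful of rules suffice. It is aimed at biocurators and text-mining
developers who need high-precision PPI evidence passages with transparent,
auditable provenance for every extraction.

## The model

For each sentence the pipeline:

1. **Parses** to a Stanford-typed dependency graph (read from CoNLL-U or the
   repo's plain-text `stanford-deps` format, or supplied by a pluggable
   parser adapter) and normalizes it to collapsed-and-propagated form:
   `prep(g,p)+pobj(p,d) ⇒ prep_p(g,d)`, and subjects/objects/prepositional
   arguments shared across conjuncts.
2. **Builds the EDG**: multi-token protein mentions merge into single
   vertices; PropBank-style numbered-argument edges `arg0`/`arg1` are added
   by a small inventory of construction rules (e.g. the passive rule
   `VBN(v) ∧ nsubjpass(v,e1) ⇒ arg1(v,e1)`, `prep_by(v,e2) ⇒ arg0(v,e2)`),
   so active, passive and nominalized realizations of a predicate receive
   identical argument labels; extra-syntactic relations — *part-whole*,
   *is-a*, *member-collection* and *coreference* (parenthesized
   abbreviations) — are detected and argument edges are propagated along
   them to fixpoint (`arg1(binds, domain) ∧ part_whole(domain, XIAP-BIR3) ⇒
   arg1(binds, XIAP-BIR3)`).
3. **Matches four rule patterns** over the numbered arguments with a
   backtracking subgraph matcher (worst case `O(n²kⁿ)`, fast in practice
   because only the argument subgraph is searched):

   | rule | pattern |
   |------|---------|
   | 1a | Protein ← arg0 ← PPI/PTM verb trigger → arg1 → Protein |
   | 1b | Protein ← arg0 ← noun trigger (complex, dimer) → arg0 → Protein |
   | 2a | Protein ← arg1 ← process trigger ← arg0 ← indirect trigger → arg1 → Protein |
   | 2b | Protein ← arg1 ← indirect trigger → arg1 → process trigger → arg1 → Protein |

4. **Detects passages**: sentences with extracted pairs are direct evidence;
   sentences that mention a *known* pair (one extracted elsewhere in the
   document) together with an experimental-technique keyword (2-hybrid,
   BIFC, cosedimentation, ITC, pulldown) or a PPI trigger are added as
   extension evidence; consecutive annotated sentences merge into passages;
   passages in the Results section (or Abstract when no Results exists),
   Results subsection titles/figure captions, or experiment-goal sentences
   ("To investigate …") are flagged as likely new, experimentally validated
   PPIs.

The trigger lexicon (PPI verbs, PTM verbs, noun/indirect/process triggers,
technique keywords) is a YAML config; `-ion` nominalizations of PPI verbs
are generated automatically (interact → interaction).

## Worked example

The shipped two-sentence fixture document has a Results-section sentence
"Kap β2B Is Associated with TAP …" and a Discussion sentence that mentions
the same two proteins plus "interaction" but in a configuration no
extraction pattern covers:

```python
from edgppi import default_lexicon, detect_passages
from edgppi.fixtures import load_kap_tap_document
from edgppi.rule_engine import extract_document_with_edgs

lex = default_lexicon()
doc, parses = load_kap_tap_document()
pairs, edgs = extract_document_with_edgs(doc, parses, lex)
for p in pairs:
    print(f"pair: {p.mention_a.text} -- {p.mention_b.text} "
          f"(trigger={p.trigger_lemma}, rule={p.rule_id}, sentence={p.sentence_index})")
for ann in detect_passages(doc, pairs, edgs, lex):
    section = doc.section_of(ann.sentence_indices[0]).name
    print(f"passage: sentences {ann.sentence_indices} [{section}] "
          f"evidence={ann.evidence} new_ppi={ann.new_ppi}")
```

prints

```
pair: Kap β2B -- TAP (trigger=associate, rule=1a, sentence=0)
passage: sentences [0] [results] evidence=direct new_ppi=True
passage: sentences [1] [discussion] evidence=trigger_cooccurrence new_ppi=False
```

The passive title sentence yields the pair through rule 1a
(`arg1(associated, Kap β2B)` from `nsubjpass`, `arg0(associated, TAP)` from
`prep_with`); it lies in Results, so the passage is flagged `new_ppi`. The
Discussion sentence is annotated only because the pair is already known from
sentence 0 and the trigger "interaction" co-occurs — remove the direct pair
and the extension disappears.

A command-line interface wraps the same pipeline:

```
edgppi extract input.bioc.xml output.bioc.xml --deps parses.deps --pairs-tsv pairs.tsv
edgppi fixtures-export fixtures.bioc.xml
edgppi score predicted_pairs.tsv gold_pairs.tsv
```

Output BioC annotations carry `type=PPI_passage`, the evidence kind, the
`new_ppi` flag and the pair list (`mentionA|mentionB|trigger|rule`).

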