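# Methods

## Sentence representation

The unit of extraction is the sentence. Each sentence is represented as a
Stanford-typed dependency graph over tokens labeled with surface text,
lowercase lemma, Penn part-of-speech tag and a half-open character span.
Graphs arrive from CoNLL-U (UD relations are translated through a fixed
table — `nsubj:pass→nsubjpass`, `obj→dobj`, `acl:relcl→rcmod`, `acl→vmod`,
`compound→nn`; `obl`/`nmod` with a `case` child are re-expanded to
`prep`+`pobj` chains; unmapped relations pass through with an `other:`
prefix), from the repository's plain-text `stanford-deps` format (labels
verbatim), or from a parser adapter. The adapter contract requires token
spans aligned to the input text and an explicit error for unparseable
input; the shipped backend is a deterministic fixture lookup, so the test
suite needs no parser model. Live backends should split trailing
`-binding`/`-interacting` participles off hyphenated compounds
("Raf-1-binding" → "Raf-1" + "binding"); the adjectival-participle
construction is unreachable otherwise.

Normalization produces the collapsed-and-propagated form the rules are
written against: prepositions fold into edge labels (`prep_of`, `prepc_by`,
`agent`), bare `conj` edges take the coordinator's lemma (`conj_and`), and
nsubj/nsubjpass/dobj/agent/prep\_\* edges are shared across conjuncts to
fixpoint. Conjunct sharing is symmetric between the conjuncts: whichever
verb the parser attached the object to, both coordinated verbs end up
carrying subject and object. Sharing is restricted to the argument-bearing
label set rather than all edges to avoid pathological duplication of
modifiers. Normalization never removes a vertex, never changes spans, and
is idempotent.

## EDG construction

**Entity merging.** Each protein mention's tokens collapse into one vertex
anchored at the span's syntactic head — the token whose governor lies
outside the span, rightmost on ties (noun phrases are right-headed).
Edges re-attach to the merged vertex; span-internal edges disappear;
duplicates collapse, so the vertex count is token count minus
Σ(mention length − 1). Overlapping mentions keep the longest (a warning is
logged); a mention overlapping no token is an error.

**Numbered arguments.** `arg0`/`arg1` edges are added at every non-entity
vertex whose lemma is a trigger or a regular variant of one (gerund:
bind → binding; `-ion` nominalization: interact → interaction,
associate → association). The construction inventory:

- **R1** active verb (VB/VBZ/VBD/VBP/VBG): `nsubj`/`xsubj` → arg0;
  `dobj`/`prep_to`/`prep_with` → arg1.
- **R2** passive participle (VBN): `nsubjpass` → arg1;
  `agent`/`prep_by` → arg0; additionally `prep_to`/`prep_with` → arg0,
  because symmetric predicates realize the second argument that way
  ("X is bound **to** Y", "X is associated **with** Y") and no agent phrase
  is present in such sentences.
- **R3** nominal with *between*: `prep_between(t,x)` → arg0;
  `conj_and(x,y)` → arg1(t,y).
- **R4** nominal with *of/to/with/by*, conditional on voice: with an
  agent/by-phrase, `prep_by` → arg0 and `prep_of` → arg1 ("activation of B
  by A"); otherwise `prep_of` → arg0 and `prep_to`/`prep_with` → arg1
  ("binding of X to Y"). For the bare process noun "activity",
  `prep_of` → arg1 (its owner is the theme the indirect rules consume).
- **R5** adjectival participle: trigger VBG/VBN under `amod`/`nn` of noun N
  with an `nn` compound dependent X → arg1(t,X), arg0(t,N).
- **R6** reduced relative: `vmod(N,t)` with t VBN → arg1(t,N); the other
  argument arrives via R2's preposition set.
- **R7** relative clause: a wh-pronoun subject under `rcmod(N,t)` is
  rewritten to N before rule application (this also covers is-a hyponym
  phrasing "X is a Y which binds Z", so no separate semantic edge is needed
  for the relative clause itself).
- **R8** null-argument gerund: a subject-less VBG under
  `prep_by`/`prepc_by` inherits the governing verb's subject (`xsubj`
  preferred).
- **R9** noun triggers (complex, dimer, …): `nn` compounds and
  `prep_of`+`conj_and` dependents all become arg0, matching rule 1b's
  double-arg0 shape.

All rules that fire on a vertex contribute; the result is the deduplicated
union. Argument-label choice for symmetric predicates does not affect pair
extraction, so ties need no arbitration beyond the union.

**Extra-syntactic relations.** *part-whole* (part → whole): a part noun
(default list: domain, region, subunit, motif, site, terminus, fragment,
cleft, residue, tail, loop) linked to an entity by
`prep_of`/`prep_in`/`nn`. *is-a* (specific → general): apposition between a
common noun and an entity (the entity side is the specific one), and
copular `nsubj`+`cop` predication. *member-collection*
(collection → member): `prep_including`/`prep_such_as` from a collection
noun, plus conjuncts of an apposed entity under a plural collection noun
("two ligands, X and Y" — the coordination contributes Y).
*coreference*: entity–entity apposition and parenthesized alias adjacency
(entity "(" entity ")"). Parenthesized aliases between two annotated
entities are accepted without a letter-matching test: biomedical aliases
("Fas ligand (FasL/CD95L)") routinely fail strict abbreviation heuristics,
and requiring both sides to be recognized entities already filters noise.

**Propagation.** For every arg edge (label, t, n): part-whole and
member-collection pass the argument from n to the whole/member; is-a passes
it from the general occurrence down to the specific; coref passes it both
ways. Added edges carry `propagated:<relation>` provenance, chains compose
to fixpoint (the edge set is bounded by 2·|V|²), and a chain never passes
through the predicate vertex itself since the intermediate edge would be a
self-loop, which the arg-edge invariant forbids. The pass is monotone and
idempotent; sem edges are applied in detection-insertion order (part-whole,
is-a, member-collection, coref) so provenance is deterministic.

## Extraction

The four rule families are expressed as labeled pattern graphs (≤ 5
vertices) over entity / trigger-class vertex predicates and
`arg0`/`arg1` edge constraints, matched by a generic backtracking matcher
that returns every injective slot assignment in lexicographic order. The
worst case is O(n²kⁿ); in practice only the argument subgraph is consulted.
A dedicated property test keeps the matcher extensionally equal to
brute-force permutation enumeration on graphs of up to 8 vertices.

Bindings whose protein slots are entity vertices become pairs. Coreferent
mentions collapse to the textually first mention of their group (so
parenthesized aliases never produce duplicate or self pairs); a pair found
by several rules in one sentence is kept once under the lowest-numbered
rule (1a > 1b > 2a > 2b priority), which stabilizes per-rule provenance
counts. Indirect-rule process triggers are "activity" plus the generated
`-ion` nominalizations only; general verbs are deliberately excluded as
indirect triggers for precision.

## Passage detection

Direct evidence: one annotation per sentence with ≥ 1 extracted pair.
Extension rules apply **only** to pairs already extracted somewhere in the
document (the known-pair index), so they raise passage recall without ever
adding an interacting partner — an invariant the tests enforce. Cross-
sentence mention matching is tolerant: names normalize by lowercasing and
hyphen/whitespace removal, aliases from document-wide coreference fold in,
and a known name matches a mention containing it as a token subsequence
("Flag-tagged STRAP" matches STRAP). Technique matching is case-insensitive
and hyphen/space tolerant over five default keywords (2-hybrid, BIFC,
cosedimentation, ITC, pulldown — config-extensible; e.g. add
coimmunoprecipitation for corpora that phrase experiments that way).
Trigger co-occurrence requires a trigger lemma in the sentence and no
extracted pair for that pair in that sentence.

Annotations on consecutive sentence indices merge into passages, never
across section boundaries; merged passages keep the strongest evidence
(direct > technique > trigger co-occurrence). One annotation is emitted per
passage (not per sentence) in the BioC output. `new_ppi` is set for
passages in the Results section (including subsection titles and figure
captions whose nearest preceding section is Results), in the Abstract only
when the document has no Results section (reading "if applicable"
strictly; configurable), or containing a sentence that starts with a goal
phrase (default: to investigate, to determine, to test, to examine — only
the first is attested, the phrasing implies an open set).

## Evaluation arithmetic

P = 100·TP/(TP+FP), R = 100·TP/(TP+FN), F = 2PR/(P+R), 0/0 ≡ 0, reported to
one decimal with half-up rounding. Pair scoring is unordered,
document-level, on normalized names with optional alias expansion; sentence
scoring is per-sentence binary, summed over documents (multi-sentence
passages are scored per sentence). Two published rows are not reproducible
from their own counts and the scorer follows the formulas: sentence recall
370/(370+197) = 65.3 (printed 64.6) and pair precision 557/(557+165) = 77.1
(printed 77.2); every other row reproduces exactly.

## Fixtures and the synthetic generator

The fixture store ships hand-built CCProcessed-style parses (plain-text
format + JSON sidecars) for all thirteen example constructs, the three
voice/nominalization variants, the part-whole propagation sentence, the
coordination/apposition sentence, and the two-sentence passage-extension
document. Hand-built parses keep the suite deterministic and
model-download-free; the cost is that they encode one plausible parse per
sentence, not parser output distributions.

The template generator instantiates the same thirteen constructs over any
PPI/PTM verb and protein names (drawn from a fixed list when a seed is
given; the seed controls name selection only — generation is otherwise
deterministic). It emulates the structural variation the representation is
designed to neutralize; it does **not** emulate parser errors, tokenizer
noise, NER errors, negation/speculation, or vocabulary outside the trigger
lexicon — passing recovery tests therefore demonstrates correctness of the
normalization-and-rules machinery on gold parses, not expected corpus-level
accuracy. Corpus-level figures require real parses and gold annotations
(the evaluator accepts generic TSV gold files for that purpose).

Problem sizes in the test and acceptance runs: 13 golden constructs, 3
voice variants, 260 synthetic template instances (13 constructs × 5 PPI
verbs × 4 name draws), 500 random graphs (≤ 8 vertices) for the matcher
oracle, 100–150 random EDGs for propagation properties. The whole suite
completes in a few seconds on one CPU.

## Known limitations

- The trigger lexicon defaults are the in-text subset (five PPI verbs,
  three PTM verbs, four noun triggers, two indirect triggers); production
  use needs a fuller curated list via the YAML config.
- No negation or speculation handling; no interaction directionality or
  bait/prey typing; genetic interactions are out of scope.
- Coreference is intra-sentential (appositions, parenthesized aliases)
  plus document-wide alias folding for passage matching; pronominal
  anaphora ("it", "this protein") is not resolved.
- The construction-rule inventory R1–R9 is a reconstruction from the
  thirteen documented constructs; corner cases outside them (e.g. unusual
  nominal argument frames) may mis-assign argument labels, though symmetric
  pair extraction is robust to label swaps.
- BioC input must already carry sentence splitting and gene/protein
  annotations; mentions crossing sentence boundaries are dropped, not
  truncated, because the sentence is the extraction unit.
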