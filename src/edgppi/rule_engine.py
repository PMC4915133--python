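"""Predicate-argument extraction rules and the subgraph matcher.

Four rule families run over a finished EDG, each expressed as a small
labeled pattern graph over ``arg0``/``arg1`` edges:

* 1a  Protein <- arg0 <- PPI/PTM verb trigger -> arg1 -> Protein
* 1b  Protein <- arg0 <- noun trigger -> arg0 -> Protein
* 2a  Protein <- arg1 <- process trigger <- arg0 <- indirect trigger -> arg1 -> Protein
* 2b  Protein <- arg1 <- indirect trigger -> arg1 -> process trigger -> arg1 -> Protein

Patterns are matched by a generic backtracking subgraph matcher whose
worst case is O(n^2 k^n) in the number of EDG vertices n and degree k; since
the patterns mention only numbered-argument labels, the search space is the
(small) argument subgraph and matching is fast in practice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .bioc_io import Document, EntityMention
from .depgraph import DependencyGraph, NoParseAvailable
from .edg_builder import EDG, build_edg
from .lexicon import TriggerLexicon, load_lexicon, default_lexicon  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

_RULE_ORDER = {"1a": 0, "1b": 1, "2a": 2, "2b": 3}


@dataclass(frozen=True)
class VertexPredicate:
    """Declarative vertex constraint: an entity vertex, a trigger vertex of a
    given class (direct/noun/indirect/process), or any vertex."""

    kind: str                      # "entity" | "trigger" | "any"
    trigger_class: str | None = None

    def holds(self, vertex, lexicon: TriggerLexicon) -> bool:
        if self.kind == "entity":
            return vertex.is_entity
        if self.kind == "any":
            return True
        if vertex.is_entity:
            return False
        checks = {
            "direct": lexicon.is_direct_trigger,
            "noun": lexicon.is_noun_trigger,
            "indirect": lexicon.is_indirect_trigger,
            "process": lexicon.is_process_trigger,
        }
        return checks[self.trigger_class](vertex.lemma)


@dataclass(frozen=True)
class RulePattern:
    """A connected labeled pattern graph of at most five vertices.  Slots are
    positional; edges are (label, from_slot, to_slot) constraints."""

    rule_id: str
    vertices: tuple[VertexPredicate, ...]
    edges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("pattern must have at least one edge")
        if len(self.vertices) > 5:
            raise ValueError("pattern exceeds five vertices")
        touched = {s for _, a, b in self.edges for s in (a, b)}
        if touched != set(range(len(self.vertices))):
            raise ValueError("pattern must be connected over its slots")


ENTITY = VertexPredicate("entity")


def _trig(cls: str) -> VertexPredicate:
    return VertexPredicate("trigger", cls)


PATTERN_1A = RulePattern("1a", (_trig("direct"), ENTITY, ENTITY),
                         (("arg0", 0, 1), ("arg1", 0, 2)))
PATTERN_1B = RulePattern("1b", (_trig("noun"), ENTITY, ENTITY),
                         (("arg0", 0, 1), ("arg0", 0, 2)))
PATTERN_2A = RulePattern("2a", (ENTITY, _trig("process"), _trig("indirect"), ENTITY),
                         (("arg1", 1, 0), ("arg0", 2, 1), ("arg1", 2, 3)))
PATTERN_2B = RulePattern("2b", (ENTITY, _trig("indirect"), _trig("process"), ENTITY),
                         (("arg1", 1, 0), ("arg1", 1, 2), ("arg1", 2, 3)))

ALL_PATTERNS = (PATTERN_1A, PATTERN_1B, PATTERN_2A, PATTERN_2B)


def match(pattern: RulePattern, edg: EDG,
          lexicon: TriggerLexicon | None = None) -> list[tuple[int, ...]]:
    """Every injective assignment of pattern slots to EDG vertex indices
    under which all vertex and edge predicates hold, in deterministic order
    (lexicographic on the bound index tuples).

    Edge constraints over ``arg0``/``arg1`` are checked against the
    numbered-argument edges; any other label is checked against the
    syntactic edges.  Patterns used by the extractor mention only numbered
    arguments, so only the argument subgraph is consulted.
    """
    lexicon = lexicon or default_lexicon()
    arg_keys = edg.arg_keys()
    syn_keys = {(e.label, e.governor, e.dependent) for e in edg.syn_edges}

    def edge_holds(label: str, gov: int, dep: int) -> bool:
        if label in ("arg0", "arg1"):
            return (label, gov, dep) in arg_keys
        return (label, gov, dep) in syn_keys

    candidates = []
    ordered = sorted(edg.vertices, key=lambda v: v.index)
    for pred in pattern.vertices:
        candidates.append([v.index for v in ordered if pred.holds(v, lexicon)])

    n = len(pattern.vertices)
    results: list[tuple[int, ...]] = []

    def backtrack(slot: int, binding: list[int]) -> None:
        if slot == n:
            results.append(tuple(binding))
            return
        for idx in candidates[slot]:
            if idx in binding:
                continue
            ok = True
            for label, a, b in pattern.edges:
                if a == slot and b < slot and not edge_holds(label, idx, binding[b]):
                    ok = False
                    break
                if b == slot and a < slot and not edge_holds(label, binding[a], idx):
                    ok = False
                    break
                if a == slot and b == slot:
                    ok = False
                    break
            if ok:
                binding.append(idx)
                backtrack(slot + 1, binding)
                binding.pop()

    backtrack(0, [])
    return sorted(results)


# ---------------------------------------------------------------------------
# PPI pairs


def normalize_name(text: str) -> str:
    """Lowercase, hyphen-free, whitespace-collapsed protein-name key."""
    return re.sub(r"[\s\-–]+", "", text.lower())


@dataclass(frozen=True)
class PPIPair:
    """An unordered pair of interacting protein mentions with provenance.
    Mentions are stored in textual order (a before b)."""

    mention_a: EntityMention
    mention_b: EntityMention
    trigger_lemma: str
    rule_id: str
    sentence_index: int
    doc_id: str = ""

    def __post_init__(self) -> None:
        if normalize_name(self.mention_a.text) == normalize_name(self.mention_b.text):
            raise ValueError("self-pair: both mentions name the same protein")
        if self.mention_a.start > self.mention_b.start:
            a, b = self.mention_a, self.mention_b
            object.__setattr__(self, "mention_a", b)
            object.__setattr__(self, "mention_b", a)

    @property
    def name_key(self) -> frozenset[str]:
        return frozenset((normalize_name(self.mention_a.text),
                          normalize_name(self.mention_b.text)))


def _coref_groups(edg: EDG) -> dict[int, int]:
    """Union-find over coref edges: vertex index -> representative index
    (textually first entity of the group)."""
    parent = {v.index: v.index for v in edg.vertices}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in edg.sem_edges:
        if s.label == "coref":
            ra, rb = find(s.source), find(s.target)
            if ra != rb:
                parent[ra] = rb
    start = {v.index: v.span[0] for v in edg.vertices}
    groups: dict[int, list[int]] = {}
    for v in edg.vertices:
        groups.setdefault(find(v.index), []).append(v.index)
    rep = {}
    for members in groups.values():
        first = min(members, key=lambda i: (start[i], i))
        for m in members:
            rep[m] = first
    return rep


def extract_pairs(edg: EDG, lexicon: TriggerLexicon,
                  sentence_index: int = 0, doc_id: str = "") -> list[PPIPair]:
    """Apply all four rule patterns to a finished EDG and return the PPI
    pairs whose protein slots bind entity vertices.

    Coreferent mentions (abbreviation aliases) are collapsed to the
    textually first mention of their group; self-pairs are removed; a pair
    found by several rules in the same sentence is kept once, under the
    lowest-numbered rule.
    """
    rep = _coref_groups(edg)
    vert = {v.index: v for v in edg.vertices}
    best: dict[frozenset[str], PPIPair] = {}
    for pattern in ALL_PATTERNS:
        for binding in match(pattern, edg, lexicon):
            if pattern.rule_id in ("1a", "1b"):
                trig_idx, a_idx, b_idx = binding
            elif pattern.rule_id == "2a":
                a_idx, _, trig_idx, b_idx = binding
            else:
                a_idx, trig_idx, _, b_idx = binding
            a_idx, b_idx = rep[a_idx], rep[b_idx]
            va, vb = vert[a_idx], vert[b_idx]
            if not (va.is_entity and vb.is_entity):
                continue
            ma, mb = va.mention_ref, vb.mention_ref
            if normalize_name(ma.text) == normalize_name(mb.text):
                continue
            pair = PPIPair(ma, mb, lexicon.base_form(vert[trig_idx].lemma),
                           pattern.rule_id, sentence_index, doc_id)
            prev = best.get(pair.name_key)
            if prev is None or _RULE_ORDER[pair.rule_id] < _RULE_ORDER[prev.rule_id]:
                best[pair.name_key] = pair
    return sorted(best.values(),
                  key=lambda p: (p.mention_a.start, p.mention_b.start, p.rule_id))


def extract_document(doc: Document, parses: dict[int, DependencyGraph],
                     lexicon: TriggerLexicon) -> list[PPIPair]:
    """Concatenate per-sentence extraction over a whole document.  ``parses``
    maps document-wide sentence index to that sentence's dependency graph;
    sentences lacking a parse are skipped with a warning."""
    pairs, _ = extract_document_with_edgs(doc, parses, lexicon)
    return pairs


def extract_document_with_edgs(
    doc: Document, parses: dict[int, DependencyGraph], lexicon: TriggerLexicon
) -> tuple[list[PPIPair], dict[int, EDG]]:
    pairs: list[PPIPair] = []
    edgs: dict[int, EDG] = {}
    for sent in doc.sentences():
        graph = parses.get(sent.index)
        if graph is None:
            log.warning("no parse for sentence %d of %s; skipped", sent.index, doc.doc_id)
            continue
        local = [m.to_local(sent.offset) for m in doc.mentions_in(sent)]
        edg = build_edg(graph, local, lexicon)
        edgs[sent.index] = edg
        for p in extract_pairs(edg, lexicon, sent.index, doc.doc_id):
            # re-express mentions in document coordinates for provenance
            pairs.append(PPIPair(
                p.mention_a.to_local(-sent.offset), p.mention_b.to_local(-sent.offset),
                p.trigger_lemma, p.rule_id, sent.index, doc.doc_id))
    return pairs, edgs


def pairs_to_tsv(pairs: list[PPIPair]) -> str:
    """TSV export: doc_id, sentence_index, mention texts, trigger, rule, offsets."""
    rows = ["doc_id\tsentence_index\tmention_a\tmention_b\ttrigger\trule_id"
            "\tstart_a\tend_a\tstart_b\tend_b"]
    for p in pairs:
        rows.append(f"{p.doc_id}\t{p.sentence_index}\t{p.mention_a.text}\t"
                    f"{p.mention_b.text}\t{p.trigger_lemma}\t{p.rule_id}\t"
                    f"{p.mention_a.start}\t{p.mention_a.end}\t"
                    f"{p.mention_b.start}\t{p.mention_b.end}")
    return "\n".join(rows) + "\n"
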