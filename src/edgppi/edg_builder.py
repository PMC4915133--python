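"""Extended dependency graph (EDG) construction.

An EDG is a sentence's dependency graph after three enrichment stages:

1. **Entity merging** — the tokens of each multi-token protein mention
   collapse into a single vertex anchored at the span's syntactic head.
2. **Numbered arguments** — PropBank-style ``arg0``/``arg1`` edges are added
   from trigger vertices to their arguments by a small inventory of
   construction rules (R1-R9 below) covering active, passive, nominalized,
   adjectival, relative-clause, reduced-relative, null-argument and
   noun-compound realizations.  The numbered arguments give a predicate the
   same argument labels no matter which surface form the sentence used.
3. **Extra-syntactic relations and propagation** — part-whole, is-a,
   member-collection and coreference (abbreviation) edges are detected, and
   argument edges are propagated along them to fixpoint, so that an argument
   that syntactically lands on "domain" or "ligands" reaches the protein
   mention itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .bioc_io import EntityMention
from .depgraph import DependencyGraph, SynEdge, normalize
from .lexicon import TriggerLexicon

log = logging.getLogger(__name__)

SEM_LABELS = ("part_whole", "is_a", "member_collection", "coref")

_ACTIVE_POS = {"VB", "VBZ", "VBD", "VBP", "VBG"}
_WH_LEMMAS = {"which", "that", "who", "whom"}
_PAREN_OPEN = {"(", "-lrb-", "["}
_PAREN_CLOSE = {")", "-rrb-", "]"}


@dataclass(frozen=True)
class EDGVertex:
    """A token vertex, possibly standing for a merged multi-token mention."""

    index: int
    text: str
    lemma: str
    pos: str
    span: tuple[int, int]
    mention_ref: EntityMention | None = None
    merged_indices: tuple[int, ...] = ()

    @property
    def is_entity(self) -> bool:
        return self.mention_ref is not None


@dataclass(frozen=True)
class ArgEdge:
    label: str                      # arg0 | arg1
    predicate: int                  # vertex index
    argument: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("arg0", "arg1"):
            raise ValueError(f"bad arg label {self.label!r}")
        if self.predicate == self.argument:
            raise ValueError("predicate and argument coincide")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.label, self.predicate, self.argument)


@dataclass(frozen=True)
class SemEdge:
    """Extra-syntactic relation.  part_whole points part -> whole,
    member_collection collection -> member, is_a specific -> general;
    coref is stored once and treated symmetrically."""

    label: str
    source: int
    target: int

    def __post_init__(self) -> None:
        if self.label not in SEM_LABELS:
            raise ValueError(f"bad semantic label {self.label!r}")


@dataclass
class EDG:
    vertices: list[EDGVertex]
    syn_edges: list[SynEdge]
    arg_edges: list[ArgEdge] = field(default_factory=list)
    sem_edges: list[SemEdge] = field(default_factory=list)

    def vertex(self, index: int) -> EDGVertex:
        for v in self.vertices:
            if v.index == index:
                return v
        raise KeyError(index)

    def syn_out(self, gov: int) -> list[SynEdge]:
        return [e for e in self.syn_edges if e.governor == gov]

    def syn_in(self, dep: int) -> list[SynEdge]:
        return [e for e in self.syn_edges if e.dependent == dep]

    def entity_vertices(self) -> list[EDGVertex]:
        return [v for v in self.vertices if v.is_entity]

    def arg_keys(self) -> set[tuple[str, int, int]]:
        return {e.key for e in self.arg_edges}

    def to_debug_lines(self) -> list[str]:
        """Line-based debug serialization ``label(pred-i, arg-j) [provenance]``."""
        name = {v.index: v.text for v in self.vertices}
        lines = []
        for e in self.arg_edges:
            lines.append(f"{e.label}({name[e.predicate]}-{e.predicate}, "
                         f"{name[e.argument]}-{e.argument}) [{e.provenance}]")
        for s in self.sem_edges:
            lines.append(f"{s.label}({name[s.source]}-{s.source}, "
                         f"{name[s.target]}-{s.target}) []")
        return lines

    def to_dot(self) -> str:
        out = ["digraph edg {"]
        for v in self.vertices:
            shape = "box" if v.is_entity else "ellipse"
            out.append(f'  n{v.index} [label="{v.text}\\n{v.pos}" shape={shape}];')
        for e in self.syn_edges:
            out.append(f'  n{e.governor} -> n{e.dependent} [label="{e.label}"];')
        for a in self.arg_edges:
            out.append(f'  n{a.predicate} -> n{a.argument} [label="{a.label}" color=blue];')
        for s in self.sem_edges:
            out.append(f'  n{s.source} -> n{s.target} [label="{s.label}" color=red];')
        out.append("}")
        return "\n".join(out)


class MentionAlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Stage 1: entity-vertex merging


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def merge_entity_tokens(graph: DependencyGraph, mentions: list[EntityMention]) -> EDG:
    """Collapse each mention's tokens into one vertex.

    Mention spans are sentence-local.  The vertex kept is the span's
    syntactic head (the token whose governor lies outside the span; rightmost
    such token on a tie, matching noun-phrase headedness).  Edges from
    absorbed vertices re-attach to the merged vertex, span-internal edges are
    deleted, and duplicates collapse.  Overlapping mentions keep the longer
    one with a warning; a mention overlapping no token is an error.
    """
    used_tokens: set[int] = set()
    chosen: list[tuple[EntityMention, list[int]]] = []
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start)):
        toks = [v.index for v in graph.vertices if _overlaps(v.span, m.span)]
        if not toks:
            raise MentionAlignmentError(
                f"mention {m.mention_id!r} ({m.text!r}) overlaps no token span")
        if any(t in used_tokens for t in toks):
            log.warning("dropping mention %r: overlaps a longer mention", m.mention_id)
            continue
        used_tokens.update(toks)
        chosen.append((m, sorted(toks)))
    chosen.sort(key=lambda pair: pair[1][0])

    gov_of = {}
    for e in graph.edges:
        gov_of.setdefault(e.dependent, e.governor)

    remap: dict[int, int] = {}
    head_info: dict[int, tuple[EntityMention, tuple[int, ...]]] = {}
    for m, toks in chosen:
        tokset = set(toks)
        heads = [t for t in toks if gov_of.get(t) not in tokset]
        head = max(heads) if heads else max(toks)
        for t in toks:
            remap[t] = head
        head_info[head] = (m, tuple(toks))

    vertices: list[EDGVertex] = []
    for v in sorted(graph.vertices, key=lambda v: v.index):
        if v.index in remap and remap[v.index] != v.index:
            continue
        if v.index in head_info:
            m, toks = head_info[v.index]
            vertices.append(EDGVertex(v.index, m.text, " ".join(m.text.lower().split()),
                                      v.pos, m.span, m, toks))
        else:
            vertices.append(EDGVertex(v.index, v.text, v.lemma, v.pos, v.span,
                                      None, (v.index,)))

    edges: list[SynEdge] = []
    seen = set()
    for e in graph.edges:
        gov = remap.get(e.governor, e.governor)
        dep = remap.get(e.dependent, e.dependent)
        if gov == dep:
            continue  # edge internal to a merged span
        key = (e.label, gov, dep)
        if key in seen:
            continue
        seen.add(key)
        edges.append(SynEdge(e.label, gov, dep))
    return EDG(vertices, edges)


# ---------------------------------------------------------------------------
# Stage 2: numbered-argument construction (rules R1-R9)


def _nominal(pos: str) -> bool:
    return pos.startswith("NN")


def add_numbered_args(edg: EDG, lexicon: TriggerLexicon) -> EDG:
    """Add ``arg0``/``arg1`` edges by applying the construction rules to every
    non-entity vertex whose lemma is a trigger (or a gerund/nominalization of
    one).  All rules that fire on a vertex contribute; the edge set is the
    union, deduplicated on (label, predicate, argument)."""
    if edg.arg_edges:
        raise ValueError("EDG already carries numbered-argument edges")

    # R7: a wh-pronoun subject inside a relative clause stands for the
    # modified noun; rewrite nsubj(t, wh) -> nsubj(t, N) for rcmod(N, t).
    work: list[SynEdge] = []
    rcmod_head = {e.dependent: e.governor for e in edg.syn_edges if e.label == "rcmod"}
    vert = {v.index: v for v in edg.vertices}
    for e in edg.syn_edges:
        if (e.label == "nsubj" and e.governor in rcmod_head
                and (vert[e.dependent].pos in ("WDT", "WP")
                     or vert[e.dependent].lemma in _WH_LEMMAS)):
            n = rcmod_head[e.governor]
            if n != e.governor:
                work.append(SynEdge("nsubj", e.governor, n))
            continue
        work.append(e)

    out: dict[int, list[SynEdge]] = {}
    inc: dict[int, list[SynEdge]] = {}
    for e in work:
        out.setdefault(e.governor, []).append(e)
        inc.setdefault(e.dependent, []).append(e)

    found: list[ArgEdge] = []
    keys: set[tuple[str, int, int]] = set()

    def add(label: str, pred: int, arg: int, rule: str) -> None:
        if pred == arg:
            return
        key = (label, pred, arg)
        if key not in keys:
            keys.add(key)
            found.append(ArgEdge(label, pred, arg, rule))

    def deps(idx: int, *labels: str) -> list[int]:
        return [e.dependent for e in out.get(idx, []) if e.label in labels]

    for v in sorted(edg.vertices, key=lambda v: v.index):
        if v.is_entity or not lexicon.is_any_trigger(v.lemma):
            continue
        t = v.index
        incoming = inc.get(t, [])

        if v.pos in _ACTIVE_POS:
            # R1: active verb (incl. gerunds): subject is arg0, object-side arg1
            for d in deps(t, "nsubj", "xsubj"):
                add("arg0", t, d, "R1")
            for d in deps(t, "dobj", "prep_to", "prep_with"):
                add("arg1", t, d, "R1")

        if v.pos == "VBN":
            # R2: passive participle: surface subject is arg1; the other
            # argument arrives by agent/by-phrase, or by to/with for
            # symmetric predicates ("X is bound to Y")
            for d in deps(t, "nsubjpass"):
                add("arg1", t, d, "R2")
            for d in deps(t, "agent", "prep_by", "prep_to", "prep_with"):
                add("arg0", t, d, "R2")

        if _nominal(v.pos):
            # R3: "interaction between X and Y"
            for x in deps(t, "prep_between"):
                add("arg0", t, x, "R3")
                for y in deps(x, "conj_and"):
                    add("arg1", t, y, "R3")
            # R4: "binding of X to Y" / "activation of Y by X"
            by = deps(t, "prep_by", "agent")
            if by:
                for d in by:
                    add("arg0", t, d, "R4")
                for d in deps(t, "prep_of"):
                    add("arg1", t, d, "R4")
            elif v.lemma == "activity":
                for d in deps(t, "prep_of"):
                    add("arg1", t, d, "R4")
            else:
                for d in deps(t, "prep_of"):
                    add("arg0", t, d, "R4")
                for d in deps(t, "prep_to", "prep_with"):
                    add("arg1", t, d, "R4")

        if v.pos in ("VBG", "VBN"):
            # R5: adjectival participle: "Raf-1-binding proteins"
            hosts = [e.governor for e in incoming if e.label in ("amod", "nn")]
            compounds = deps(t, "nn")
            if hosts and compounds:
                for x in compounds:
                    add("arg1", t, x, "R5")
                for n in hosts:
                    add("arg0", t, n, "R5")
            # R6: reduced relative: "ERK2 bound to PEA-15"
            if v.pos == "VBN":
                for e in incoming:
                    if e.label == "vmod":
                        add("arg1", t, e.governor, "R6")

        if v.pos == "VBG":
            # R8: null-argument gerund under "by": inherit the governing
            # verb's subject ("X represses ... by binding to Y")
            has_subj = bool(deps(t, "nsubj", "xsubj"))
            if not has_subj:
                for e in incoming:
                    if e.label in ("prep_by", "prepc_by"):
                        g = e.governor
                        subj = deps(g, "xsubj") or deps(g, "nsubj")
                        for s in subj:
                            add("arg0", t, s, "R8")

        if lexicon.is_noun_trigger(v.lemma):
            # R9: non-verbal noun trigger: "X-Y complex", "complex of X and Y"
            members = deps(t, "nn")
            for x in deps(t, "prep_of"):
                members.append(x)
                members.extend(deps(x, "conj_and"))
            for x in members:
                add("arg0", t, x, "R9")

    return EDG(edg.vertices, edg.syn_edges, found, list(edg.sem_edges))


# ---------------------------------------------------------------------------
# Stage 3a: extra-syntactic relation detection


def detect_extra_relations(edg: EDG, lexicon: TriggerLexicon) -> EDG:
    """Detect part-whole, is-a, member-collection and coreference edges.

    * part-whole: a part noun (``domain``, ``subunit``, ...) linked to an
      entity by ``prep_of``/``prep_in``/``nn``.
    * is-a: apposition between a common noun and an entity, and copular
      "X is a Y" (relative-clause hyponymy is handled by the wh-substitution
      of rule R7, so no extra edge is needed for it).
    * member-collection: a plural collection noun linked to entities by
      ``prep_including``/``prep_such_as``, or by apposition followed by
      coordination over entity vertices.
    * coref: two entity vertices in apposition, and parenthesized
      abbreviation/alias pairs (entity "(" entity ")" adjacency).
    """
    vert = {v.index: v for v in edg.vertices}
    sem: list[SemEdge] = []
    seen: set[tuple[str, int, int]] = set()

    def add(label: str, src: int, tgt: int) -> None:
        if src == tgt:
            return
        key = (label, src, tgt)
        if key not in seen:
            seen.add(key)
            sem.append(SemEdge(label, src, tgt))

    appos = [(e.governor, e.dependent) for e in edg.syn_edges if e.label == "appos"]
    conj_and = {}
    for e in edg.syn_edges:
        if e.label.startswith("conj_"):
            conj_and.setdefault(e.governor, []).append(e.dependent)

    # part-whole
    for v in sorted(edg.vertices, key=lambda v: v.index):
        if v.is_entity or v.lemma not in lexicon.part_nouns:
            continue
        for e in edg.syn_out(v.index):
            if e.label in ("prep_of", "prep_in", "nn") and vert[e.dependent].is_entity:
                add("part_whole", v.index, e.dependent)

    # is-a from apposition (entity side is the specific one)
    for g, d in appos:
        ge, de = vert[g].is_entity, vert[d].is_entity
        if ge and de:
            continue  # entity-entity apposition is coreference, below
        if de and not ge:
            add("is_a", d, g)
        elif ge and not de:
            add("is_a", g, d)
        else:
            add("is_a", d, g)

    # is-a from copula: nsubj(pred_nominal, X) + cop(pred_nominal, be)
    cops = {e.governor for e in edg.syn_edges if e.label == "cop"}
    for n in cops:
        if not _nominal(vert[n].pos):
            continue
        for e in edg.syn_out(n):
            if e.label == "nsubj":
                add("is_a", e.dependent, n)

    # member-collection
    for v in sorted(edg.vertices, key=lambda v: v.index):
        if v.is_entity:
            continue
        plural = v.pos == "NNS"
        for e in edg.syn_out(v.index):
            if e.label in ("prep_including", "prep_such_as") and vert[e.dependent].is_entity:
                add("member_collection", v.index, e.dependent)
                for m in conj_and.get(e.dependent, []):
                    if vert[m].is_entity:
                        add("member_collection", v.index, m)
            elif plural and e.label == "appos" and vert[e.dependent].is_entity:
                for m in conj_and.get(e.dependent, []):
                    if vert[m].is_entity:
                        add("member_collection", v.index, m)

    # coref: entity-entity apposition
    for g, d in appos:
        if vert[g].is_entity and vert[d].is_entity:
            add("coref", g, d)

    # coref: parenthesized alias "LONG ( SHORT )" by span adjacency
    ordered = sorted(edg.vertices, key=lambda v: v.span[0])
    for i, u in enumerate(ordered):
        if not u.is_entity:
            continue
        rest = ordered[i + 1:]
        if len(rest) >= 2 and rest[0].text.lower() in _PAREN_OPEN and rest[1].is_entity:
            if len(rest) >= 3 and rest[2].text.lower() not in _PAREN_CLOSE:
                continue
            add("coref", u.index, rest[1].index)

    return EDG(edg.vertices, edg.syn_edges, list(edg.arg_edges), sem)


# ---------------------------------------------------------------------------
# Stage 3b: argument propagation


def propagate_args(edg: EDG) -> EDG:
    """Propagate numbered arguments along semantic edges to fixpoint.

    For every ArgEdge(label, t, n): part_whole(n, m) and
    member_collection(n, m) pass the argument on to m; is_a(m, n) passes it
    from the general occurrence n down to the specific m; coref passes it in
    both directions.  Added edges carry ``propagated:<relation>``
    provenance.  The pass is monotone and idempotent; the edge set is
    bounded by 2·|V|² so iteration terminates.
    """
    args: list[ArgEdge] = list(edg.arg_edges)
    keys = {a.key for a in args}

    def add(label: str, pred: int, arg: int, rel: str) -> bool:
        if pred == arg or (label, pred, arg) in keys:
            return False
        keys.add((label, pred, arg))
        args.append(ArgEdge(label, pred, arg, f"propagated:{rel}"))
        return True

    changed = True
    while changed:
        changed = False
        for a in list(args):
            for s in edg.sem_edges:
                if s.label in ("part_whole", "member_collection") and s.source == a.argument:
                    changed |= add(a.label, a.predicate, s.target, s.label)
                elif s.label == "is_a" and s.target == a.argument:
                    changed |= add(a.label, a.predicate, s.source, "is_a")
                elif s.label == "coref" and a.argument in (s.source, s.target):
                    other = s.target if a.argument == s.source else s.source
                    changed |= add(a.label, a.predicate, other, "coref")
    return EDG(edg.vertices, edg.syn_edges, args, list(edg.sem_edges))


# ---------------------------------------------------------------------------
# Pipeline convenience


def build_edg(graph: DependencyGraph, mentions: list[EntityMention],
              lexicon: TriggerLexicon) -> EDG:
    """Full EDG construction: normalize -> merge -> numbered args ->
    extra-syntactic relations -> propagation."""
    if not graph.normalized:
        graph = normalize(graph)
    edg = merge_entity_tokens(graph, mentions)
    edg = add_numbered_args(edg, lexicon)
    edg = detect_extra_relations(edg, lexicon)
    return propagate_args(edg)
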