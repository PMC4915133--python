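"""Per-sentence dependency graphs.

A :class:`DependencyGraph` holds one sentence's tokens (with lemma, Penn
part-of-speech tag and character span) and labeled directed syntactic edges
using Stanford typed-dependency names (``nsubj``, ``dobj``, ``prep_of`` ...).
Graphs can be ingested from CoNLL-U files, from the repository's plain-text
"stanford-deps" format, or from a pluggable parser adapter, and normalized to
collapsed-and-propagated (CCProcessed-style) form: prepositions are folded
into edge labels and argument-bearing dependencies are propagated across
conjuncts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

#: Closed set of Stanford-style labels the downstream rules know about.
KNOWN_LABELS = frozenset(
    {
        "nsubj", "nsubjpass", "dobj", "iobj", "agent", "appos", "cop",
        "rcmod", "vmod", "nn", "amod", "xsubj", "xcomp", "ccomp", "advmod",
        "aux", "auxpass", "det", "num", "dep", "poss", "mark", "punct",
        "prep", "pobj", "pcomp", "cc", "conj", "neg", "expl", "parataxis",
    }
)

_COLLAPSED_RE = re.compile(r"^(prep|prepc|conj)_[a-z0-9_]+$")

#: UD v2 relation -> Stanford typed-dependency translation.
_UD_TO_STANFORD = {
    "nsubj": "nsubj",
    "nsubj:pass": "nsubjpass",
    "obj": "dobj",
    "iobj": "iobj",
    "obl:agent": "agent",
    "acl:relcl": "rcmod",
    "acl": "vmod",
    "compound": "nn",
    "appos": "appos",
    "amod": "amod",
    "advmod": "advmod",
    "cop": "cop",
    "aux": "aux",
    "aux:pass": "auxpass",
    "det": "det",
    "nummod": "num",
    "nmod:poss": "poss",
    "mark": "mark",
    "punct": "punct",
    "cc": "cc",
    "xcomp": "xcomp",
    "ccomp": "ccomp",
    "expl": "expl",
    "parataxis": "parataxis",
    "neg": "neg",
}

#: Labels duplicated across conjuncts during normalization.  Restricted to
#: the argument-bearing set the extraction rules consult.
_PROPAGATE_LABELS = ("nsubj", "nsubjpass", "dobj", "agent")


def _is_propagatable(label: str) -> bool:
    return label in _PROPAGATE_LABELS or label.startswith("prep_") or label.startswith("prepc_")


@dataclass(frozen=True)
class TokenVertex:
    """One token: 1-based position, surface text, lowercase lemma, Penn tag,
    half-open character span in sentence-local coordinates."""

    index: int
    text: str
    lemma: str
    pos: str
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lemma", self.lemma.lower())


@dataclass(frozen=True)
class SynEdge:
    """Directed labeled dependency governor -> dependent (token indices)."""

    label: str
    governor: int
    dependent: int

    def __post_init__(self) -> None:
        if self.governor == self.dependent:
            raise ValueError(f"self-loop on token {self.governor} ({self.label})")


def canonical_label(label: str) -> str:
    """Map a raw label into the declared closed set, collapsed labels, or the
    ``other:`` escape prefix."""
    if label in KNOWN_LABELS or _COLLAPSED_RE.match(label):
        return label
    if label.startswith("other:"):
        return label
    return f"other:{label}"


@dataclass
class DependencyGraph:
    vertices: list[TokenVertex]
    edges: list[SynEdge]
    normalized: bool = False
    sent_id: str = ""

    def __post_init__(self) -> None:
        idx = {v.index for v in self.vertices}
        if len(idx) != len(self.vertices):
            raise ValueError("duplicate token indices")
        for e in self.edges:
            if e.governor not in idx or e.dependent not in idx:
                raise ValueError(f"edge {e.label}({e.governor},{e.dependent}) endpoint missing")

    def vertex(self, index: int) -> TokenVertex:
        for v in self.vertices:
            if v.index == index:
                return v
        raise KeyError(index)

    def text(self) -> str:
        return " ".join(v.text for v in sorted(self.vertices, key=lambda v: v.index))


class ParseError(ValueError):
    """Raised for malformed parse files (bad index, cycle, multiple roots)."""


# ---------------------------------------------------------------------------
# CoNLL-U ingestion


def _check_tree(heads: dict[int, int], sent_no: int) -> None:
    roots = [i for i, h in heads.items() if h == 0]
    if len(roots) != 1:
        raise ParseError(f"sentence {sent_no}: expected exactly one root, found {len(roots)}")
    for start in heads:
        seen = set()
        node = start
        while node != 0:
            if node in seen:
                raise ParseError(f"sentence {sent_no}: cyclic head chain at token {start}")
            seen.add(node)
            node = heads[node]


def read_conllu(path) -> list[DependencyGraph]:
    """Read a CoNLL-U file into per-sentence graphs with basic (uncollapsed)
    Stanford-style labels.

    UD relations are translated through a fixed table; ``obl``/``nmod`` with a
    ``case`` child are re-expanded to ``prep``/``pobj`` chains so that
    :func:`normalize` produces collapsed ``prep_X`` labels; ``conj`` becomes
    ``conj_<coordinator lemma>`` using the conjunct's ``cc`` child.  Unmapped
    labels pass through with an ``other:`` prefix.
    """
    with open(path, encoding="utf-8") as fh:
        content = fh.read()
    graphs: list[DependencyGraph] = []
    for sent_no, block in enumerate(_blocks(content)):
        rows = []
        sent_id = ""
        for line in block:
            if line.startswith("#"):
                m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
                if m:
                    sent_id = m.group(1)
                continue
            cols = line.split("\t")
            if "-" in cols[0] or "." in cols[0]:
                continue  # multiword-token / empty-node lines
            if len(cols) < 8:
                raise ParseError(f"sentence {sent_no}: short CoNLL-U row: {line!r}")
            rows.append(cols)
        if not rows:
            continue
        heads = {int(c[0]): int(c[6]) for c in rows}
        _check_tree(heads, sent_no)
        deprel = {int(c[0]): c[7] for c in rows}
        lemma_of = {int(c[0]): (c[2] if c[2] != "_" else c[1]).lower() for c in rows}

        vertices: list[TokenVertex] = []
        offset = 0
        for c in rows:
            i, text = int(c[0]), c[1]
            vertices.append(
                TokenVertex(i, text, lemma_of[i], c[4] if c[4] != "_" else c[3],
                            (offset, offset + len(text)))
            )
            offset += len(text) + 1

        case_child = {}
        cc_child = {}
        for i, h in heads.items():
            if deprel[i] == "case":
                case_child[h] = i
            elif deprel[i] == "cc":
                cc_child[h] = i

        edges: list[SynEdge] = []
        for i, h in heads.items():
            if h == 0:
                continue
            rel = deprel[i].lower()
            base = rel.split(":")[0]
            if rel in ("case", "cc"):
                continue  # consumed below / attached to conj label
            if base in ("obl", "nmod") and rel not in ("nmod:poss", "obl:agent"):
                if i in case_child:
                    p = case_child[i]
                    edges.append(SynEdge("prep", h, p))
                    edges.append(SynEdge("pobj", p, i))
                else:
                    edges.append(SynEdge(canonical_label(rel), h, i))
                continue
            if base == "conj":
                coord = lemma_of.get(cc_child.get(i, -1), "and")
                edges.append(SynEdge(f"conj_{coord}", h, i))
                continue
            edges.append(SynEdge(canonical_label(_UD_TO_STANFORD.get(rel, rel)), h, i))
        graphs.append(DependencyGraph(vertices, edges, normalized=False, sent_id=sent_id))
    return graphs


def _blocks(content: str):
    block: list[str] = []
    for line in content.splitlines():
        if line.strip():
            block.append(line)
        elif block:
            yield block
            block = []
    if block:
        yield block


# ---------------------------------------------------------------------------
# stanford-deps text format

_TOKEN_ROW = re.compile(r"^(\d+)\t([^\t]+)\t([^\t]+)\t([^\t]+)(?:\t(\d+)\t(\d+))?$")
_EDGE_ROW = re.compile(r"^([A-Za-z_:0-9]+)\(([^()]*?)-(\d+),\s*([^()]*?)-(\d+)\)$")


def read_stanford_deps(path) -> list[DependencyGraph]:
    """Read the repository's plain-text dependency format.

    Each blank-line-separated sentence block holds a token header — one
    tab-separated row ``index<TAB>text<TAB>lemma<TAB>pos[<TAB>start<TAB>end]``
    per token — followed by edge lines ``label(govText-govIdx, depText-depIdx)``.
    ``root(ROOT-0, x-i)`` lines are accepted and skipped.  Labels are taken
    verbatim; the graph is flagged normalized when any collapsed label
    (``prep_*``/``conj_*``) occurs.
    """
    with open(path, encoding="utf-8") as fh:
        content = fh.read()
    return parse_stanford_deps(content)


def parse_stanford_deps(content: str) -> list[DependencyGraph]:
    graphs = []
    for sent_no, block in enumerate(_blocks(content)):
        vertices: list[TokenVertex] = []
        edges: list[SynEdge] = []
        sent_id = ""
        offset = 0
        for line in block:
            if line.startswith("#"):
                m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
                if m:
                    sent_id = m.group(1)
                continue
            m = _TOKEN_ROW.match(line)
            if m:
                i = int(m.group(1))
                text = m.group(2)
                if m.group(5) is not None:
                    span = (int(m.group(5)), int(m.group(6)))
                else:
                    span = (offset, offset + len(text))
                offset = span[1] + 1
                vertices.append(TokenVertex(i, text, m.group(3), m.group(4), span))
                continue
            m = _EDGE_ROW.match(line)
            if m:
                label, gov, dep = m.group(1), int(m.group(3)), int(m.group(5))
                if label == "root" and gov == 0:
                    continue
                known = {v.index for v in vertices}
                if gov not in known or dep not in known:
                    raise ParseError(
                        f"sentence {sent_no}: token index out of range in {line!r}")
                edges.append(SynEdge(canonical_label(label), gov, dep))
                continue
            raise ParseError(f"sentence {sent_no}: unrecognized line {line!r}")
        if not vertices:
            continue
        normalized = any(_COLLAPSED_RE.match(e.label) for e in edges)
        graphs.append(DependencyGraph(vertices, edges, normalized=normalized, sent_id=sent_id))
    return graphs


def write_stanford_deps(graphs: list[DependencyGraph], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_stanford_deps(graphs))


def format_stanford_deps(graphs: list[DependencyGraph]) -> str:
    out = []
    for g in graphs:
        lines = []
        if g.sent_id:
            lines.append(f"# sent_id = {g.sent_id}")
        by_index = {v.index: v for v in g.vertices}
        for v in sorted(g.vertices, key=lambda v: v.index):
            lines.append(f"{v.index}\t{v.text}\t{v.lemma}\t{v.pos}\t{v.span[0]}\t{v.span[1]}")
        for e in g.edges:
            lines.append(
                f"{e.label}({by_index[e.governor].text}-{e.governor}, "
                f"{by_index[e.dependent].text}-{e.dependent})"
            )
        out.append("\n".join(lines))
    return "\n\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Normalization to CCProcessed-style form


def normalize(graph: DependencyGraph) -> DependencyGraph:
    """Collapse prepositions into edge labels and propagate argument-bearing
    dependencies across conjuncts.

    ``prep(g, p) + pobj(p, d)`` becomes ``prep_<lemma(p)>(g, d)``;
    ``prep(g, p) + pcomp(p, d)`` becomes ``prepc_<lemma(p)>(g, d)``;
    ``agent(g, p) + pobj(p, d)`` becomes ``agent(g, d)``.  Then, for each
    ``conj_<c>(a, b)``, every nsubj/nsubjpass/dobj/agent/prep_* edge incident
    to ``a`` is duplicated onto ``b`` in the same role, to fixpoint across
    conjunct chains.  Vertices and token spans are untouched; the operation
    is idempotent.
    """
    edges = list(graph.edges)

    # --- preposition collapsing
    pobj_of = {}
    pcomp_of = {}
    for e in edges:
        if e.label == "pobj":
            pobj_of[e.governor] = e.dependent
        elif e.label == "pcomp":
            pcomp_of[e.governor] = e.dependent
    lemma = {v.index: v.lemma for v in graph.vertices}
    collapsed: list[SynEdge] = []
    consumed_preps = set()
    for e in edges:
        if e.label == "prep" and e.dependent in pobj_of:
            collapsed.append(SynEdge(f"prep_{lemma[e.dependent]}", e.governor, pobj_of[e.dependent]))
            consumed_preps.add(e.dependent)
        elif e.label == "prep" and e.dependent in pcomp_of:
            collapsed.append(SynEdge(f"prepc_{lemma[e.dependent]}", e.governor, pcomp_of[e.dependent]))
            consumed_preps.add(e.dependent)
        elif e.label == "agent" and e.dependent in pobj_of:
            collapsed.append(SynEdge("agent", e.governor, pobj_of[e.dependent]))
            consumed_preps.add(e.dependent)
        else:
            collapsed.append(e)
    edges = [
        e for e in collapsed
        if not (e.label in ("pobj", "pcomp") and e.governor in consumed_preps)
    ]

    # --- bare conj: fold the coordinator lemma into the label (conj_and)
    cc_of = {}
    for e in edges:
        if e.label == "cc":
            cc_of.setdefault(e.governor, lemma[e.dependent])
    edges = [
        SynEdge(f"conj_{cc_of.get(e.governor, 'and')}", e.governor, e.dependent)
        if e.label == "conj" else e
        for e in edges
    ]

    # --- conjunct propagation (fixpoint over conj chains)
    edge_set = {(e.label, e.governor, e.dependent) for e in edges}
    conj_pairs = []
    for e in edges:
        if e.label.startswith("conj_"):
            # sharing works both ways: each conjunct inherits the other's
            # subjects/objects/prepositional arguments
            conj_pairs.append((e.governor, e.dependent))
            conj_pairs.append((e.dependent, e.governor))
    changed = True
    while changed:
        changed = False
        for a, b in conj_pairs:
            for label, gov, dep in list(edge_set):
                if not _is_propagatable(label):
                    continue
                new = None
                if gov == a and dep != b:
                    new = (label, b, dep)
                elif dep == a and gov != b:
                    new = (label, gov, b)
                if new and new not in edge_set:
                    edge_set.add(new)
                    changed = True
    order = {(e.label, e.governor, e.dependent): i for i, e in enumerate(edges)}
    final = sorted(edge_set, key=lambda t: (order.get(t, len(order)), t))
    return DependencyGraph(
        vertices=list(graph.vertices),
        edges=[SynEdge(*t) for t in final],
        normalized=True,
        sent_id=graph.sent_id,
    )


# ---------------------------------------------------------------------------
# Parser adapter contract


class NoParseAvailable(LookupError):
    """The configured backend has no parse for the requested sentence."""


class ParserAdapter:
    """Contract for pluggable sentence parsers.

    Implementations return a :class:`DependencyGraph` whose token spans align
    with the input text.  Backends for live parsers should wrap their
    tokenizer with a retokenizer that splits trailing ``-binding`` /
    ``-interacting`` participles off hyphenated entity compounds
    ("Raf-1-binding" -> "Raf-1" + "binding"), matching the convention the
    fixture graphs use.
    """

    def parse(self, sentence_text: str) -> DependencyGraph:
        raise NotImplementedError


class FixtureParserAdapter(ParserAdapter):
    """Deterministic test backend: a lookup from known sentence text to
    hand-built graphs.  Unknown sentences raise, never return an empty graph."""

    def __init__(self, table: dict[str, DependencyGraph]):
        self._table = {self._key(k): v for k, v in table.items()}

    @staticmethod
    def _key(text: str) -> str:
        return " ".join(text.split())

    def parse(self, sentence_text: str) -> DependencyGraph:
        key = self._key(sentence_text)
        if key not in self._table:
            raise NoParseAvailable(f"no parse available for: {sentence_text!r}")
        return self._table[key]
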