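"""Synthetic sentence templates for the thirteen constructs.

Each template instantiates one construct's sentence skeleton and gold
dependency graph with a chosen trigger verb and protein names, together
with the pairs a correct extraction must recover.  Generation is a pure
function of (construct, trigger, names, seed); the seed only selects names
when none are given.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from ..bioc_io import EntityMention
from ..depgraph import DependencyGraph, SynEdge, TokenVertex
from ..lexicon import default_lexicon, gerund, ion_nominalization
from .cases import FixtureCase

#: Protein-like names the seeded generator draws from.
PROTEIN_NAMES = (
    "BRCA1", "TP53", "MDM2", "CDK2", "AKT1", "RAF1", "GRB2", "SMAD3",
    "STAT3", "NFKB1", "EGFR", "SRC", "JAK2", "PTEN", "MYC", "HSP90",
    "UBC9", "RAD51", "CHK2", "PLK1",
)

_IRREGULAR_PARTICIPLES = {"bind": "bound"}


class TemplateError(ValueError):
    pass


def _v3s(verb: str) -> str:
    return verb + "es" if verb.endswith(("s", "x", "ch", "sh")) else verb + "s"


def _participle(verb: str) -> str:
    if verb in _IRREGULAR_PARTICIPLES:
        return _IRREGULAR_PARTICIPLES[verb]
    return verb + "d" if verb.endswith("e") else verb + "ed"


def _nominal(verb: str) -> str:
    return ion_nominalization(verb) or gerund(verb)


@dataclass(frozen=True)
class TemplateSpec:
    construct: str
    trigger: str
    names: tuple[str, ...] | None = None
    seed: int = 0


def _graph(tokens: list[tuple[str, str, str]], edges: list[tuple[str, int, int]],
           ) -> DependencyGraph:
    vertices = []
    offset = 0
    for i, (text, lemma, pos) in enumerate(tokens, start=1):
        vertices.append(TokenVertex(i, text, lemma, pos, (offset, offset + len(text))))
        offset += len(text) + 1
    return DependencyGraph(vertices, [SynEdge(l, g, d) for l, g, d in edges])


def _tok(name: str) -> tuple[str, str, str]:
    return (name, name.lower(), "NN")


# Each builder returns (tokens, edges, mention token indices, expected pairs
# as index tuples into names).
def _active(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), _tok(n[1]), (".", ".", ".")],
            [("nsubj", 2, 1), ("dobj", 2, 3), ("punct", 2, 4)],
            [1, 3], [(0, 1)])


def _passive(v, n):
    return ([_tok(n[1]), ("is", "be", "VBZ"), (_participle(v), v, "VBN"),
             ("by", "by", "IN"), _tok(n[0]), (".", ".", ".")],
            [("nsubjpass", 3, 1), ("auxpass", 3, 2), ("prep", 3, 4),
             ("pobj", 4, 5), ("punct", 3, 6)],
            [1, 5], [(0, 1)])


def _nominalization(v, n):
    nom = _nominal(v)
    return ([(nom.capitalize(), nom, "NN"), ("of", "of", "IN"), _tok(n[0]),
             ("to", "to", "TO"), _tok(n[1]), ("was", "be", "VBD"),
             ("observed", "observe", "VBN"), (".", ".", ".")],
            [("prep", 1, 2), ("pobj", 2, 3), ("prep", 1, 4), ("pobj", 4, 5),
             ("nsubjpass", 7, 1), ("auxpass", 7, 6), ("punct", 7, 8)],
            [3, 5], [(0, 1)])


def _adjective(v, n):
    g = gerund(v)
    return ([_tok(n[0]), (g, v, "VBG"), ("proteins", "protein", "NNS"),
             (",", ",", ","), _tok(n[1]), (".", ".", ".")],
            [("nn", 2, 1), ("amod", 3, 2), ("punct", 3, 4), ("appos", 3, 5),
             ("punct", 3, 6)],
            [1, 5], [(0, 1)])


def _full_relative(v, n):
    return ([_tok(n[0]), (",", ",", ","), ("which", "which", "WDT"),
             (_v3s(v), v, "VBZ"), _tok(n[1]), (".", ".", ".")],
            [("punct", 1, 2), ("rcmod", 1, 4), ("nsubj", 4, 3), ("dobj", 4, 5),
             ("punct", 1, 6)],
            [1, 5], [(0, 1)])


def _reduced_relative(v, n):
    return ([("Structure", "structure", "NN"), ("of", "of", "IN"), _tok(n[0]),
             (_participle(v), v, "VBN"), ("to", "to", "TO"), _tok(n[1]),
             ("was", "be", "VBD"), ("solved", "solve", "VBN"), (".", ".", ".")],
            [("nsubjpass", 8, 1), ("prep", 1, 2), ("pobj", 2, 3), ("vmod", 3, 4),
             ("prep", 4, 5), ("pobj", 5, 6), ("auxpass", 8, 7), ("punct", 8, 9)],
            [3, 6], [(0, 1)])


def _coordination(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), _tok(n[1]), ("and", "and", "CC"),
             _tok(n[2]), (".", ".", ".")],
            [("nsubj", 2, 1), ("dobj", 2, 3), ("cc", 3, 4), ("conj", 3, 5),
             ("punct", 2, 6)],
            [1, 3, 5], [(0, 1), (0, 2)])


def _null_argument(v, n):
    g = gerund(v)
    return ([_tok(n[0]), ("can", "can", "MD"), ("function", "function", "VB"),
             ("by", "by", "IN"), (g, v, "VBG"), ("to", "to", "TO"), _tok(n[1]),
             (".", ".", ".")],
            [("nsubj", 3, 1), ("aux", 3, 2), ("prep", 3, 4), ("pcomp", 4, 5),
             ("prep", 5, 6), ("pobj", 6, 7), ("punct", 3, 8)],
            [1, 7], [(0, 1)])


def _is_a(v, n):
    return ([_tok(n[0]), ("is", "be", "VBZ"), ("an", "a", "DT"),
             ("antigen", "antigen", "NN"), ("which", "which", "WDT"),
             (_v3s(v), v, "VBZ"), _tok(n[1]), (".", ".", ".")],
            [("nsubj", 4, 1), ("cop", 4, 2), ("det", 4, 3), ("rcmod", 4, 6),
             ("nsubj", 6, 5), ("dobj", 6, 7), ("punct", 4, 8)],
            [1, 7], [(0, 1)])


def _appositive(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), ("its", "its", "PRP$"),
             ("receptor", "receptor", "NN"), (",", ",", ","), _tok(n[1]),
             (".", ".", ".")],
            [("nsubj", 2, 1), ("dobj", 2, 4), ("poss", 4, 3), ("punct", 4, 5),
             ("appos", 4, 6), ("punct", 2, 7)],
            [1, 6], [(0, 1)])


def _member_collection(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), ("multiple", "multiple", "JJ"),
             ("proteins", "protein", "NNS"), (",", ",", ","),
             ("including", "including", "VBG"), _tok(n[1]), (".", ".", ".")],
            [("nsubj", 2, 1), ("dobj", 2, 4), ("amod", 4, 3), ("punct", 4, 5),
             ("prep", 4, 6), ("pobj", 6, 7), ("punct", 2, 8)],
            [1, 7], [(0, 1)])


def _part_whole(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), ("to", "to", "TO"), ("a", "a", "DT"),
             ("domain", "domain", "NN"), ("in", "in", "IN"), _tok(n[1]),
             (".", ".", ".")],
            [("nsubj", 2, 1), ("prep", 2, 3), ("pobj", 3, 5), ("det", 5, 4),
             ("prep", 5, 6), ("pobj", 6, 7), ("punct", 2, 8)],
            [1, 7], [(0, 1)])


def _combination(v, n):
    return ([_tok(n[0]), (_v3s(v), v, "VBZ"), ("two", "two", "CD"),
             ("ligands", "ligand", "NNS"), (",", ",", ","), _tok(n[1]),
             ("and", "and", "CC"), _tok(n[2]), (".", ".", ".")],
            [("nsubj", 2, 1), ("dobj", 2, 4), ("num", 4, 3), ("punct", 4, 5),
             ("appos", 4, 6), ("cc", 6, 7), ("conj", 6, 8), ("punct", 2, 9)],
            [1, 6, 8], [(0, 1), (0, 2)])


TEMPLATE_CONSTRUCTS = {
    "active": (_active, 2),
    "passive": (_passive, 2),
    "nominalization": (_nominalization, 2),
    "adjective": (_adjective, 2),
    "full_relative": (_full_relative, 2),
    "reduced_relative": (_reduced_relative, 2),
    "coordination": (_coordination, 3),
    "null_argument": (_null_argument, 2),
    "is_a": (_is_a, 2),
    "appositive": (_appositive, 2),
    "member_collection": (_member_collection, 2),
    "part_whole": (_part_whole, 2),
    "combination": (_combination, 3),
}


def generate(spec: TemplateSpec) -> FixtureCase:
    """Instantiate a construct template as a :class:`FixtureCase`.

    The trigger must be a PPI/PTM verb of the default lexicon (the thirteen
    constructs all realize verbal predicates; a noun trigger like "complex"
    has no slot in them and raises :class:`TemplateError`)."""
    if spec.construct not in TEMPLATE_CONSTRUCTS:
        raise TemplateError(
            f"unknown construct {spec.construct!r}; choose from "
            f"{sorted(TEMPLATE_CONSTRUCTS)}")
    lex = default_lexicon()
    if not (spec.trigger in lex.ppi_verbs or spec.trigger in lex.ptm_verbs):
        raise TemplateError(
            f"trigger {spec.trigger!r} is not a PPI/PTM verb; the "
            f"{spec.construct!r} template requires a verbal trigger")
    builder, arity = TEMPLATE_CONSTRUCTS[spec.construct]
    if spec.names is None:
        rng = random.Random(spec.seed)
        names = tuple(rng.sample(PROTEIN_NAMES, arity))
    else:
        names = tuple(spec.names)
    if len(names) != arity:
        raise TemplateError(f"{spec.construct!r} needs {arity} names, got {len(names)}")
    if len(set(names)) != arity:
        raise TemplateError("entity names must be distinct")

    tokens, edges, mention_idx, pair_idx = builder(spec.trigger, names)
    graph = _graph(tokens, edges)
    sentence = " ".join(t[0] for t in tokens)
    span_of = {v.index: v.span for v in graph.vertices}
    mentions = [
        EntityMention(f"m{k}", sentence[span_of[i][0]:span_of[i][1]],
                      span_of[i][0], span_of[i][1])
        for k, i in enumerate(mention_idx)
    ]
    expected = {frozenset({names[a], names[b]}) for a, b in pair_idx}
    case_id = f"{spec.construct}:{spec.trigger}:{'-'.join(names)}"
    return FixtureCase(case_id, sentence, mentions, graph, expected, [spec.construct])
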