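import random

import pytest

from edgppi.bioc_io import EntityMention
from edgppi.depgraph import DependencyGraph, SynEdge, TokenVertex
from edgppi.edg_builder import EDG, ArgEdge, EDGVertex, SemEdge
from edgppi.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_graph(tokens, edges, normalized=False):
    """tokens: list of (text, lemma, pos); edges: (label, gov, dep) 1-based."""
    vertices = []
    offset = 0
    for i, (text, lemma, pos) in enumerate(tokens, start=1):
        vertices.append(TokenVertex(i, text, lemma, pos, (offset, offset + len(text))))
        offset += len(text) + 1
    return DependencyGraph(vertices, [SynEdge(*e) for e in edges], normalized=normalized)


def make_mention(text, start, end, mid="m"):
    return EntityMention(mid, text, start, end)


def random_tree(rng, n):
    """A random labeled dependency tree over n tokens (token i's head < i)."""
    tokens = [(f"w{i}", f"w{i}", "NN") for i in range(1, n + 1)]
    labels = ["nsubj", "dobj", "amod", "nn", "det", "advmod", "dep"]
    edges = []
    for i in range(2, n + 1):
        head = rng.randint(1, i - 1)
        edges.append((rng.choice(labels), head, i))
    return make_graph(tokens, edges)


def random_edg(rng, max_vertices=8, lexicon=None):
    """A small random EDG with entity/trigger/filler vertices and random
    numbered-argument edges, for matcher and propagation property tests."""
    lexicon = lexicon or default_lexicon()
    n = rng.randint(2, max_vertices)
    trigger_lemmas = (sorted(lexicon.ppi_verbs) + sorted(lexicon.noun_triggers)
                      + sorted(lexicon.indirect_triggers)
                      + sorted(lexicon.process_triggers))
    vertices = []
    for i in range(1, n + 1):
        kind = rng.random()
        start = (i - 1) * 5
        if kind < 0.4:
            name = f"P{i}"
            m = EntityMention(f"m{i}", name, start, start + len(name))
            vertices.append(EDGVertex(i, name, name.lower(), "NN",
                                      (start, start + len(name)), m, (i,)))
        elif kind < 0.8:
            lemma = rng.choice(trigger_lemmas)
            vertices.append(EDGVertex(i, lemma, lemma, "VBZ",
                                      (start, start + len(lemma)), None, (i,)))
        else:
            vertices.append(EDGVertex(i, f"w{i}", f"w{i}", "NN",
                                      (start, start + 2), None, (i,)))
    args = []
    seen = set()
    for _ in range(rng.randint(0, 2 * n)):
        a, b = rng.sample(range(1, n + 1), 2)
        label = rng.choice(["arg0", "arg1"])
        if (label, a, b) not in seen:
            seen.add((label, a, b))
            args.append(ArgEdge(label, a, b, "random"))
    sems = []
    for _ in range(rng.randint(0, n // 2)):
        a, b = rng.sample(range(1, n + 1), 2)
        sems.append(SemEdge(rng.choice(["part_whole", "is_a",
                                        "member_collection", "coref"]), a, b))
    return EDG(vertices, [], args, sems)
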