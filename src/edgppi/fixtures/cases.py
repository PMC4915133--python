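"""Loading the shipped fixture cases."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from ..bioc_io import Document, EntityMention, Section, Sentence
from ..depgraph import DependencyGraph, FixtureParserAdapter, parse_stanford_deps


@dataclass
class FixtureCase:
    case_id: str
    sentence: str
    mentions: list[EntityMention]          # sentence-local spans
    graph: DependencyGraph
    expected_pairs: set[frozenset[str]]    # unordered surface-name pairs
    construct_tags: list[str]


def _data_dir():
    return resources.files("edgppi.fixtures").joinpath("data")


def available_cases() -> list[str]:
    names = []
    for entry in _data_dir().iterdir():
        if entry.name.endswith(".json") and not entry.name.startswith("_"):
            names.append(entry.name[:-5])
    return sorted(names)


def load_fixture(case_id: str) -> FixtureCase:
    """Load one stored case by id (e.g. ``table1_row01``); unknown ids raise
    with the list of available ids."""
    data = _data_dir()
    json_path = data.joinpath(f"{case_id}.json")
    if not json_path.is_file():
        raise KeyError(f"unknown fixture {case_id!r}; available: {available_cases()}")
    meta = json.loads(json_path.read_text())
    graphs = parse_stanford_deps(data.joinpath(f"{case_id}.deps").read_text())
    if len(graphs) != 1:
        raise ValueError(f"fixture {case_id}: expected one sentence block")
    graph = graphs[0]
    sentence = " ".join(v.text for v in sorted(graph.vertices, key=lambda v: v.index))
    span_of = {v.index: v.span for v in graph.vertices}
    mentions = []
    for i, m in enumerate(meta["mentions"]):
        first, last = m["tokens"]
        start, end = span_of[first][0], span_of[last][1]
        mentions.append(EntityMention(m.get("id", f"{case_id}.m{i}"),
                                      sentence[start:end], start, end,
                                      m.get("type", "protein")))
    return FixtureCase(
        case_id=case_id,
        sentence=sentence,
        mentions=mentions,
        graph=graph,
        expected_pairs={frozenset(p) for p in meta["expected_pairs"]},
        construct_tags=list(meta.get("construct_tags", [])),
    )


def fixture_parser_adapter(case_ids: list[str] | None = None) -> FixtureParserAdapter:
    """A parser adapter backed by the shipped gold parses."""
    ids = case_ids if case_ids is not None else available_cases()
    return FixtureParserAdapter({load_fixture(c).sentence: load_fixture(c).graph
                                 for c in ids})


def load_kap_tap_document() -> tuple[Document, dict[int, DependencyGraph]]:
    """The two-sentence Kap β2B / TAP document: a Results-section sentence
    where extraction finds the pair, and a Discussion sentence that mentions
    the pair and the trigger "interaction" but matches no pattern."""
    s1 = load_fixture("kap_tap_s1")
    s2 = load_fixture("kap_tap_s2")
    off2 = len(s1.sentence) + 1
    doc = Document(
        "kap_tap",
        sections=[
            Section("results", [Sentence(s1.sentence, 0, 0)]),
            Section("discussion", [Sentence(s2.sentence, off2, 1)]),
        ],
    )
    for m in s1.mentions:
        doc.mentions.append(m)
    for m in s2.mentions:
        doc.mentions.append(EntityMention(m.mention_id, m.text,
                                          m.start + off2, m.end + off2, m.entity_type))
    parses = {0: s1.graph, 1: s2.graph}
    return doc, parses


def export_bioc(path, case_ids: list[str] | None = None) -> list[Document]:
    """Write fixture cases as a one-sentence-per-document BioC collection
    (for end-to-end I/O tests) and return the documents."""
    from ..bioc_io import write_collection

    ids = case_ids if case_ids is not None else available_cases()
    docs = []
    for cid in ids:
        case = load_fixture(cid)
        doc = Document(cid, [Section("results", [Sentence(case.sentence, 0, 0)])],
                       list(case.mentions))
        docs.append(doc)
    write_collection(docs, {}, path)
    return docs
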