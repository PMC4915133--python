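"""EDG construction: merging, numbered arguments, semantic relations,
propagation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgppi.bioc_io import EntityMention
from edgppi.edg_builder import (EDG, ArgEdge, MentionAlignmentError, SemEdge,
                                add_numbered_args, build_edg,
                                detect_extra_relations, merge_entity_tokens,
                                propagate_args)
from edgppi.depgraph import normalize
from edgppi.fixtures import load_fixture

from conftest import make_graph, random_edg, random_tree


def _edg_for(case_id, lexicon):
    case = load_fixture(case_id)
    return build_edg(case.graph, case.mentions, lexicon), case


def _arg_set(edg, lexicon, entity_only=True):
    out = set()
    for e in edg.arg_edges:
        arg = edg.vertex(e.argument)
        if entity_only and not arg.is_entity:
            continue
        out.add((e.label, lexicon.base_form(edg.vertex(e.predicate).lemma), arg.text))
    return out


class TestMergeEntityTokens:
    def test_single_token_mention_keeps_structure(self):
        g = normalize(make_graph(
            [("HFE", "hfe", "NN"), ("binds", "bind", "VBZ"), ("B", "b", "NN")],
            [("nsubj", 2, 1), ("dobj", 2, 3)]))
        m = EntityMention("m1", "HFE", 0, 3)
        edg = merge_entity_tokens(g, [m])
        assert len(edg.vertices) == 3
        assert edg.vertex(1).mention_ref == m
        assert {(e.label, e.governor, e.dependent) for e in edg.syn_edges} == \
            {(e.label, e.governor, e.dependent) for e in g.edges}

    def test_multi_token_merge_vertex_count_formula(self, lexicon):
        case = load_fixture("table1_row02")
        merged = merge_entity_tokens(normalize(case.graph), case.mentions)
        shrink = sum(len([v for v in case.graph.vertices
                          if v.span[0] < m.end and m.start < v.span[1]]) - 1
                     for m in case.mentions)
        assert len(merged.vertices) == len(case.graph.vertices) - shrink
        ent = [v for v in merged.vertices if v.is_entity]
        assert any(v.text.startswith("Plasminogen") for v in ent)

    def test_random_merges_leave_no_dangling_edges(self):
        rng = random.Random(11)
        for _ in range(30):
            n = rng.randint(3, 10)
            g = random_tree(rng, n)
            first = rng.randint(1, n - 1)
            width = rng.randint(1, min(3, n - first))
            span = (g.vertex(first).span[0], g.vertex(first + width).span[1])
            m = EntityMention("m", "X" * (span[1] - span[0]), span[0], span[1])
            edg = merge_entity_tokens(g, [m])
            idx = {v.index for v in edg.vertices}
            for e in edg.syn_edges:
                assert e.governor in idx and e.dependent in idx
            assert len(edg.vertices) == n - width

    def test_overlapping_mentions_keep_longer(self, caplog):
        g = make_graph([("Kap", "kap", "NN"), ("B2B", "b2b", "NN")], [("nn", 2, 1)],
                       normalized=True)
        long = EntityMention("long", "Kap B2B", 0, 7)
        short = EntityMention("short", "Kap", 0, 3)
        with caplog.at_level("WARNING"):
            edg = merge_entity_tokens(g, [short, long])
        assert [v.mention_ref.mention_id for v in edg.vertices if v.is_entity] == ["long"]

    def test_mention_without_token_overlap_rejected(self):
        g = make_graph([("A", "a", "NN")], [], normalized=True)
        with pytest.raises(MentionAlignmentError):
            merge_entity_tokens(g, [EntityMention("m", "Z", 50, 52)])


class TestAddNumberedArgs:
    def test_voice_and_nominalization_invariance(self, lexicon):
        sets = []
        for cid in ("fig1_active", "fig1_passive", "fig1_nominal"):
            edg, _ = _edg_for(cid, lexicon)
            sets.append(_arg_set(edg, lexicon))
        assert sets[0] == {("arg0", "activate", "STAT1"), ("arg1", "activate", "IRF1")}
        assert sets[0] == sets[1] == sets[2]

    def test_passive_construction_rule(self, lexicon):
        edg, _ = _edg_for("fig1_passive", lexicon)
        by_rule = {(e.label, e.provenance) for e in edg.arg_edges}
        assert ("arg1", "R2") in by_rule and ("arg0", "R2") in by_rule

    def test_no_trigger_no_args(self, lexicon):
        g = make_graph([("A", "a", "NN"), ("sees", "see", "VBZ"), ("B", "b", "NN")],
                       [("nsubj", 2, 1), ("dobj", 2, 3)], normalized=True)
        edg = merge_entity_tokens(g, [EntityMention("m1", "A", 0, 1),
                                      EntityMention("m2", "B", 7, 8)])
        assert add_numbered_args(edg, lexicon).arg_edges == []

    def test_predicate_lemmas_are_triggers(self, lexicon):
        from edgppi.fixtures import available_cases
        for cid in available_cases():
            edg, _ = _edg_for(cid, lexicon)
            for e in edg.arg_edges:
                assert lexicon.is_any_trigger(edg.vertex(e.predicate).lemma), (cid, e)


class TestDetectExtraRelations:
    def test_part_whole_from_prep_in(self, lexicon):
        edg, _ = _edg_for("table1_row12", lexicon)
        rels = {(s.label, edg.vertex(s.source).lemma, edg.vertex(s.target).text)
                for s in edg.sem_edges}
        assert ("part_whole", "domain", "XIAP-BIR3") in rels

    def test_member_collection_from_including(self, lexicon):
        edg, _ = _edg_for("table1_row11", lexicon)
        rels = {(s.label, edg.vertex(s.source).lemma, edg.vertex(s.target).text)
                for s in edg.sem_edges}
        assert ("member_collection", "protein", "RAD9") in rels

    def test_plain_sentence_has_no_sem_edges(self, lexicon):
        edg, _ = _edg_for("fig1_active", lexicon)
        assert edg.sem_edges == []

    def test_parenthesized_alias_coref(self, lexicon):
        edg, _ = _edg_for("table1_row13", lexicon)
        corefs = {frozenset({edg.vertex(s.source).text, edg.vertex(s.target).text})
                  for s in edg.sem_edges if s.label == "coref"}
        assert frozenset({"Fas ligand", "FasL/CD95L"}) in corefs


class TestPropagateArgs:
    def test_part_whole_propagation_reaches_entity(self, lexicon):
        edg, _ = _edg_for("arts", lexicon)
        args = _arg_set(edg, lexicon)
        assert args == {("arg0", "bind", "ARTS"), ("arg1", "bind", "XIAP-BIR3")}
        prov = {e.provenance for e in edg.arg_edges
                if edg.vertex(e.argument).text == "XIAP-BIR3"}
        assert prov == {"propagated:part_whole"}

    def test_no_sem_edges_is_identity(self):
        edg = EDG([], [], [], [])
        assert propagate_args(edg).arg_edges == []

    def test_chain_matches_transitive_closure(self, lexicon):
        # independent oracle: BFS closure over the propagation relation
        rng = random.Random(23)
        for _ in range(50):
            edg = random_edg(rng, lexicon=lexicon)
            result = propagate_args(edg)
            expected = set()
            for a in edg.arg_edges:
                reach = {a.argument}
                frontier = [a.argument]
                while frontier:
                    x = frontier.pop()
                    for s in edg.sem_edges:
                        nxt = None
                        if s.label in ("part_whole", "member_collection") and s.source == x:
                            nxt = s.target
                        elif s.label == "is_a" and s.target == x:
                            nxt = s.source
                        elif s.label == "coref" and x in (s.source, s.target):
                            nxt = s.target if x == s.source else s.source
                        # a chain cannot pass through the predicate itself:
                        # the intermediate edge would be a self-loop
                        if nxt is not None and nxt not in reach and nxt != a.predicate:
                            reach.add(nxt)
                            frontier.append(nxt)
                for r in reach:
                    if r != a.predicate:
                        expected.add((a.label, a.predicate, r))
            got = {k for k in result.arg_keys()}
            assert expected <= got
            # nothing beyond the closure of the original edges
            assert got <= expected | {a.key for a in edg.arg_edges}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_and_monotone(self, seed):
        rng = random.Random(seed)
        edg = random_edg(rng)
        once = propagate_args(edg)
        twice = propagate_args(once)
        assert once.arg_keys() == twice.arg_keys()
        assert {a.key for a in edg.arg_edges} <= once.arg_keys()

    def test_spans_and_vertices_untouched(self, lexicon):
        case = load_fixture("table1_row12")
        edg = build_edg(case.graph, case.mentions, lexicon)
        non_entity = [v for v in edg.vertices if not v.is_entity]
        originals = {v.index: v.span for v in case.graph.vertices}
        for v in non_entity:
            assert v.span == originals[v.index]


class TestFig3Constructs:
    def test_one_coordination_three_appositions(self, lexicon):
        edg, _ = _edg_for("fig3", lexicon)
        appos_derived = [e for e in edg.arg_edges if e.label == "arg1"
                         and e.provenance in ("propagated:is_a", "propagated:coref")]
        coord_derived = [e for e in edg.arg_edges if e.label == "arg1"
                         and e.provenance == "propagated:member_collection"]
        assert len(appos_derived) == 3
        assert len(coord_derived) == 1
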