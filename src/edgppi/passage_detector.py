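"""PPI passage detection over whole documents.

Direct evidence comes from sentences where the predicate-argument rules
extracted a pair.  Two non-predicate rules then extend coverage — but only
over pairs already known to interact somewhere else in the article, so they
raise passage recall without adding new interacting partners:

* **technique**: a sentence mentioning both members of a known pair plus an
  experimental-technique keyword (2-hybrid, BIFC, cosedimentation, ITC,
  pulldown);
* **trigger co-occurrence**: a sentence mentioning both members of a known
  pair plus a PPI trigger, where no extraction pattern applied.

Annotated sentences on consecutive indices merge into passages, and each
passage is flagged as likely reporting a new, experimentally validated PPI
from its position in the article (Results section, Results subsection
titles and figure captions, or experiment-goal sentences such as those
beginning "to investigate").
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict

from .bioc_io import Document, PassageAnnotation, Sentence
from .edg_builder import EDG
from .lexicon import TriggerLexicon
from .rule_engine import PPIPair, normalize_name

log = logging.getLogger(__name__)

_EVIDENCE_RANK = {"direct": 0, "technique": 1, "trigger_cooccurrence": 2}


class KnownPairIndex:
    """Document-wide index of extracted pairs keyed by normalized unordered
    name pairs, with coref/abbreviation aliases folded in.

    A sentence mention matches a known name tolerantly: its normalized form
    contains the known name as a token subsequence (so "Flag-tagged STRAP"
    matches "STRAP")."""

    def __init__(self, pairs: list[PPIPair], aliases: dict[str, set[str]] | None = None):
        self._index: dict[frozenset[str], list[PPIPair]] = defaultdict(list)
        self._aliases = {k: set(v) for k, v in (aliases or {}).items()}
        for p in pairs:
            self._index[p.name_key].append(p)

    def __len__(self) -> int:
        return len(self._index)

    def known_pairs(self) -> list[frozenset[str]]:
        return sorted(self._index, key=sorted)

    def supporting(self, key: frozenset[str]) -> list[PPIPair]:
        return self._index.get(key, [])

    def _name_matches(self, known: str, mention_text: str) -> bool:
        m = normalize_name(mention_text)
        if known in (m,) or known in self._aliases.get(m, ()):
            return True
        # token-subsequence containment on the raw mention
        toks = [normalize_name(t) for t in mention_text.split()]
        for i in range(len(toks)):
            acc = ""
            for j in range(i, len(toks)):
                acc += toks[j]
                if acc == known:
                    return True
        return known != "" and known in m and len(known) >= 3

    def pairs_in(self, mention_texts: list[str]) -> list[frozenset[str]]:
        """Known pairs for which two distinct mentions in the list match the
        two member names."""
        found = []
        for key in self.known_pairs():
            names = sorted(key)
            if len(names) != 2:
                continue
            a, b = names
            hit_a = [t for t in mention_texts if self._name_matches(a, t)]
            hit_b = [t for t in mention_texts if self._name_matches(b, t)]
            if hit_a and hit_b and (len(set(hit_a + hit_b)) > 1):
                found.append(key)
        return found


def collect_aliases(edgs: dict[int, EDG]) -> dict[str, set[str]]:
    """Document-wide alias sets from per-sentence coref edges: each
    normalized name maps to the normalized names it corefers with."""
    aliases: dict[str, set[str]] = defaultdict(set)
    for edg in edgs.values():
        vert = {v.index: v for v in edg.vertices}
        for s in edg.sem_edges:
            if s.label != "coref":
                continue
            a = normalize_name(vert[s.source].text)
            b = normalize_name(vert[s.target].text)
            aliases[a].add(b)
            aliases[b].add(a)
    return dict(aliases)


def build_known_index(pairs: list[PPIPair], edgs: dict[int, EDG] | None = None
                      ) -> KnownPairIndex:
    return KnownPairIndex(pairs, collect_aliases(edgs or {}))


# ---------------------------------------------------------------------------
# Selection rules


def select_direct(doc: Document, pairs: list[PPIPair]) -> list[PassageAnnotation]:
    """One direct-evidence annotation per sentence containing >= 1 pair."""
    by_sentence: dict[int, list[PPIPair]] = defaultdict(list)
    for p in pairs:
        by_sentence[p.sentence_index].append(p)
    return [PassageAnnotation([i], "direct", by_sentence[i])
            for i in sorted(by_sentence)]


def _normalize_keyword(s: str) -> str:
    return re.sub(r"[\s\-]+", "", s.lower())


def sentence_has_technique(sentence: Sentence, lexicon: TriggerLexicon) -> bool:
    hay = _normalize_keyword(sentence.text)
    return any(_normalize_keyword(k) in hay for k in lexicon.technique_keywords)


def extend_by_technique(doc: Document, known: KnownPairIndex,
                        lexicon: TriggerLexicon,
                        exclude: set[int] | None = None) -> list[PassageAnnotation]:
    """Technique-evidence annotations: sentences that mention both members of
    a known pair together with an experimental-technique keyword."""
    exclude = exclude or set()
    out = []
    for sent in doc.sentences():
        if sent.index in exclude:
            continue
        if not sentence_has_technique(sent, lexicon):
            continue
        texts = [m.text for m in doc.mentions_in(sent)]
        if len(texts) < 2:
            continue
        if known.pairs_in(texts):
            out.append(PassageAnnotation([sent.index], "technique"))
    return out


def _sentence_trigger_lemmas(edg: EDG, lexicon: TriggerLexicon) -> list[str]:
    return [v.lemma for v in edg.vertices
            if not v.is_entity and lexicon.is_any_trigger(v.lemma)]


def extend_by_trigger(doc: Document, known: KnownPairIndex,
                      lexicon: TriggerLexicon, edgs: dict[int, EDG],
                      pairs: list[PPIPair]) -> list[PassageAnnotation]:
    """Trigger-co-occurrence annotations: sentences mentioning both members
    of a known pair plus a PPI trigger lemma, where the extraction rules
    found nothing for that pair in that sentence."""
    extracted_here: dict[int, set[frozenset[str]]] = defaultdict(set)
    for p in pairs:
        extracted_here[p.sentence_index].add(p.name_key)
    out = []
    for sent in doc.sentences():
        edg = edgs.get(sent.index)
        if edg is None:
            continue
        if not _sentence_trigger_lemmas(edg, lexicon):
            continue
        texts = [m.text for m in doc.mentions_in(sent)]
        if len(texts) < 2:
            continue
        hit = [k for k in known.pairs_in(texts)
               if k not in extracted_here.get(sent.index, ())]
        if hit:
            out.append(PassageAnnotation([sent.index], "trigger_cooccurrence"))
    return out


def assemble_passages(annotations: list[PassageAnnotation],
                      doc: Document | None = None) -> list[PassageAnnotation]:
    """Merge annotations on consecutive sentence indices into single
    passages; the merged passage unions the pair lists and keeps the
    strongest evidence label (direct > technique > trigger_cooccurrence).
    When ``doc`` is given, runs never merge across section boundaries."""
    by_sentence: dict[int, list[PassageAnnotation]] = defaultdict(list)
    for ann in annotations:
        for i in ann.sentence_indices:
            by_sentence[i].append(ann)
    if not by_sentence:
        return []

    def same_section(a: int, b: int) -> bool:
        return doc is None or doc.section_of(a) is doc.section_of(b)

    runs: list[list[int]] = []
    for i in sorted(by_sentence):
        if runs and i == runs[-1][-1] + 1 and same_section(runs[-1][-1], i):
            runs[-1].append(i)
        else:
            runs.append([i])
    merged = []
    for run in runs:
        anns = [a for i in run for a in by_sentence[i]]
        evidence = min((a.evidence for a in anns), key=_EVIDENCE_RANK.__getitem__)
        pairs: list[PPIPair] = []
        seen = set()
        for a in anns:
            for p in a.pairs:
                k = (p.name_key, p.sentence_index)
                if k not in seen:
                    seen.add(k)
                    pairs.append(p)
        if evidence == "direct" and not pairs:
            evidence = "trigger_cooccurrence"
        merged.append(PassageAnnotation(run, evidence, pairs))
    return merged


# ---------------------------------------------------------------------------
# New-PPI heuristics


def _starts_with_goal_phrase(text: str, lexicon: TriggerLexicon) -> bool:
    lead = text.lstrip(" \t\"'“”‘’([").lower()
    return any(lead.startswith(g) for g in lexicon.goal_phrases)


def flag_new_ppi(passages: list[PassageAnnotation], doc: Document,
                 lexicon: TriggerLexicon) -> list[PassageAnnotation]:
    """Set ``new_ppi`` on passages likely to report experimentally validated
    interactions: passages in the Results section (or, for documents without
    one, the Abstract), Results subsection titles, Results figure captions,
    or passages whose first sentence states an experiment goal.  Pure
    function of section labels and sentence text; re-running is a no-op."""
    has_results = any(sec.name == "results" and not sec.is_title
                      for sec in doc.sections)
    out = []
    for p in passages:
        flag = False
        for i in p.sentence_indices:
            sec = doc.section_of(i)
            if sec.name == "results":
                flag = True  # Results body, subsection title, or caption
            elif sec.name == "fig-caption" and _in_results_span(doc, i):
                flag = True
            elif sec.name == "abstract" and not has_results:
                flag = True
            elif _starts_with_goal_phrase(doc.sentence(i).text, lexicon):
                flag = True
        out.append(PassageAnnotation(list(p.sentence_indices), p.evidence,
                                     list(p.pairs), flag))
    return out


def _in_results_span(doc: Document, sentence_index: int) -> bool:
    """A figure caption belongs to Results when the nearest preceding
    non-caption section is the Results section."""
    current = None
    for sec in doc.sections:
        if sec.name != "fig-caption":
            current = sec.name
        if any(s.index == sentence_index for s in sec.sentences):
            return current == "results"
    return False


# ---------------------------------------------------------------------------
# Full pipeline


def detect_passages(doc: Document, pairs: list[PPIPair], edgs: dict[int, EDG],
                    lexicon: TriggerLexicon) -> list[PassageAnnotation]:
    """Direct selection, both extension rules, assembly, and new-PPI
    flagging, in order."""
    direct = select_direct(doc, pairs)
    direct_idx = {i for a in direct for i in a.sentence_indices}
    known = build_known_index(pairs, edgs)
    technique = extend_by_technique(doc, known, lexicon, exclude=direct_idx)
    tech_idx = {i for a in technique for i in a.sentence_indices}
    trigger = [a for a in extend_by_trigger(doc, known, lexicon, edgs, pairs)
               if a.sentence_indices[0] not in direct_idx | tech_idx]
    passages = assemble_passages(direct + technique + trigger, doc)
    return flag_new_ppi(passages, doc, lexicon)


def passages_to_tsv(doc: Document, passages: list[PassageAnnotation]) -> str:
    rows = ["doc_id\tsentences\tevidence\tnew_ppi\tpairs"]
    for p in passages:
        pair_str = ";".join(
            f"{q.mention_a.text}|{q.mention_b.text}|{q.trigger_lemma}|{q.rule_id}"
            for q in p.pairs)
        span = f"{p.sentence_indices[0]}-{p.sentence_indices[-1]}"
        rows.append(f"{doc.doc_id}\t{span}\t{p.evidence}\t{str(p.new_ppi).lower()}\t{pair_str}")
    return "\n".join(rows) + "\n"
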