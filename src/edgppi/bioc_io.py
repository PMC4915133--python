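"""BioC XML collections: documents, sentence-level passages, protein mentions.

Implements the subset of BioC 1.0 this pipeline consumes and produces:
collections of documents whose passages carry section-type infons and
pre-split sentences, entity annotations with character offsets, and — on
output — passage-level PPI-evidence annotations.  All spans are 0-based,
half-open, in document coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .rule_engine import PPIPair

log = logging.getLogger(__name__)

#: Controlled vocabulary of section names; unrecognized types map to "other".
SECTION_VOCAB = ("title", "abstract", "intro", "methods", "results",
                 "discussion", "fig-caption", "other")

#: Table-driven mapping from BioC passage section infons (lowercased) to the
#: controlled vocabulary; extend via the ``section_map`` argument.
DEFAULT_SECTION_MAP = {
    "title": "title",
    "front": "title",
    "abstract": "abstract",
    "intro": "intro",
    "introduction": "intro",
    "background": "intro",
    "method": "methods",
    "methods": "methods",
    "materials and methods": "methods",
    "results": "results",
    "result": "results",
    "results and discussion": "results",
    "discussion": "discussion",
    "discuss": "discussion",
    "conclusion": "discussion",
    "fig": "fig-caption",
    "figure": "fig-caption",
    "fig-caption": "fig-caption",
    "fig_caption": "fig-caption",
    "caption": "fig-caption",
}

#: Entity annotation types accepted, matched case-insensitively as substrings.
DEFAULT_ENTITY_TYPES = ("gene", "protein")


@dataclass(frozen=True)
class EntityMention:
    """A gene/protein name occurrence; span is [start, end) in document
    coordinates and ``text`` equals the document substring at that span."""

    mention_id: str
    text: str
    start: int
    end: int
    entity_type: str = "protein"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"mention {self.mention_id}: empty span [{self.start},{self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def to_local(self, sentence_offset: int) -> "EntityMention":
        """The same mention in sentence-local coordinates."""
        return EntityMention(self.mention_id, self.text,
                             self.start - sentence_offset, self.end - sentence_offset,
                             self.entity_type)


@dataclass(frozen=True)
class Sentence:
    text: str
    offset: int          # 0-based character offset into document text
    index: int           # document-wide sentence ordinal

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


@dataclass
class Section:
    name: str
    sentences: list[Sentence] = field(default_factory=list)
    is_title: bool = False   # subsection-title passage (BioC "title_1" etc.)

    def __post_init__(self) -> None:
        if self.name not in SECTION_VOCAB:
            raise ValueError(f"unknown section name {self.name!r}")


@dataclass
class Document:
    doc_id: str
    sections: list[Section] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)

    def sentences(self) -> list[Sentence]:
        return [s for sec in self.sections for s in sec.sentences]

    def sentence(self, index: int) -> Sentence:
        for s in self.sentences():
            if s.index == index:
                return s
        raise KeyError(index)

    def section_of(self, sentence_index: int) -> Section:
        for sec in self.sections:
            for s in sec.sentences:
                if s.index == sentence_index:
                    return sec
        raise KeyError(sentence_index)

    def mentions_in(self, sentence: Sentence) -> list[EntityMention]:
        return [m for m in self.mentions
                if m.start >= sentence.offset and m.end <= sentence.end]


EVIDENCE_KINDS = ("direct", "technique", "trigger_cooccurrence")


@dataclass
class PassageAnnotation:
    """One or more consecutive sentences flagged as PPI evidence."""

    sentence_indices: list[int]
    evidence: str
    pairs: list["PPIPair"] = field(default_factory=list)
    new_ppi: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.evidence!r}")
        idx = self.sentence_indices
        if not idx or any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("sentence_indices must be consecutive ascending integers")
        if self.evidence == "direct" and not self.pairs:
            raise ValueError("direct evidence requires a non-empty pair list")


class BioCValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reading


def _map_section(raw: str, section_map: dict[str, str]) -> tuple[str, bool]:
    key = (raw or "").strip().lower()
    is_title = False
    # "title_1"/"title_2" mark (sub)section headings in PMC-style BioC;
    # "<name>_title" is this writer's own encoding of the same thing.
    if key.startswith("title_") and key[6:].isdigit():
        is_title = True
        key = "title"
    elif key.endswith("_title"):
        is_title = True
        key = key[: -len("_title")]
    name = section_map.get(key)
    if name is None:
        # try prefix match ("fig_caption_ref" -> fig)
        for k, v in section_map.items():
            if key.startswith(k):
                name = v
                break
    return (name or "other"), is_title


def read_collection(
    path,
    *,
    entity_types: Iterable[str] = DEFAULT_ENTITY_TYPES,
    section_map: dict[str, str] | None = None,
) -> list[Document]:
    """Read a BioC XML collection into :class:`Document` objects.

    Entity annotations whose infon type matches one of ``entity_types``
    (case-insensitive substring) become mentions; mentions whose spans cross
    sentence boundaries are dropped with a logged warning; an annotation
    offset outside the covered text raises :class:`BioCValidationError`.
    """
    section_map = dict(DEFAULT_SECTION_MAP if section_map is None else section_map)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise BioCValidationError(f"malformed BioC XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "collection":
        raise BioCValidationError(f"expected <collection> root, found <{root.tag}>")

    documents: list[Document] = []
    accepted = tuple(t.lower() for t in entity_types)
    for doc_el in root.findall("document"):
        doc_id = (doc_el.findtext("id") or "").strip()
        sections: list[Section] = []
        mentions: list[EntityMention] = []
        sent_index = 0
        for pas_el in doc_el.findall("passage"):
            infons = {i.get("key"): (i.text or "") for i in pas_el.findall("infon")}
            raw_type = infons.get("section_type") or infons.get("type") or ""
            name, is_title = _map_section(raw_type, section_map)
            section = Section(name, [], is_title)
            pas_offset = int(pas_el.findtext("offset") or 0)
            pas_text = pas_el.findtext("text")
            sent_els = pas_el.findall("sentence")
            if sent_els:
                for s_el in sent_els:
                    s_off = int(s_el.findtext("offset") or 0)
                    s_text = s_el.findtext("text") or ""
                    section.sentences.append(Sentence(s_text, s_off, sent_index))
                    sent_index += 1
                    for a_el in s_el.findall("annotation"):
                        m = _read_annotation(a_el, accepted, doc_id)
                        if m:
                            mentions.append(m)
            elif pas_text is not None:
                # passage without sentence splitting: treat as one sentence
                section.sentences.append(Sentence(pas_text, pas_offset, sent_index))
                sent_index += 1
            for a_el in pas_el.findall("annotation"):
                m = _read_annotation(a_el, accepted, doc_id)
                if m:
                    mentions.append(m)
            sections.append(section)
        doc = Document(doc_id, sections, [])
        _attach_mentions(doc, mentions)
        documents.append(doc)
    return documents


def _read_annotation(a_el, accepted: tuple[str, ...], doc_id: str) -> EntityMention | None:
    infons = {i.get("key"): (i.text or "") for i in a_el.findall("infon")}
    atype = (infons.get("type") or "").lower()
    if not any(t in atype for t in accepted):
        return None
    loc = a_el.find("location")
    if loc is None:
        raise BioCValidationError(f"annotation {a_el.get('id')!r} in {doc_id} has no location")
    start = int(loc.get("offset"))
    length = int(loc.get("length"))
    text = a_el.findtext("text") or ""
    return EntityMention(a_el.get("id") or "", text, start, start + length,
                         "gene" if "gene" in atype else "protein")


def _attach_mentions(doc: Document, mentions: list[EntityMention]) -> None:
    """Resolve mentions to sentences; drop boundary-crossing ones, validate
    that each mention's text matches the sentence substring."""
    sentences = doc.sentences()
    doc_end = max((s.end for s in sentences), default=0)
    for m in mentions:
        if m.end > doc_end:
            raise BioCValidationError(
                f"annotation {m.mention_id!r} span [{m.start},{m.end}) outside "
                f"document text of {doc.doc_id} (ends at {doc_end})")
        host = [s for s in sentences if m.start >= s.offset and m.end <= s.end]
        if not host:
            log.warning("dropping mention %r in %s: span [%d,%d) crosses a sentence "
                        "boundary", m.mention_id, doc.doc_id, m.start, m.end)
            continue
        sent = host[0]
        covered = sent.text[m.start - sent.offset: m.end - sent.offset]
        if m.text and covered != m.text:
            raise BioCValidationError(
                f"annotation {m.mention_id!r} text {m.text!r} does not match "
                f"document substring {covered!r}")
        doc.mentions.append(m)
    doc.mentions.sort(key=lambda m: (m.start, m.end, m.mention_id))


# ---------------------------------------------------------------------------
# Writing


def write_collection(
    documents: list[Document],
    annotations: dict[str, list[PassageAnnotation]] | None,
    path,
    *,
    source: str = "edgppi",
) -> None:
    """Write documents (and optional per-document passage annotations) as a
    BioC XML collection.

    Each :class:`PassageAnnotation` becomes one ``<annotation>`` element on
    the passage containing its first sentence, carrying the covered character
    range and infons ``type=PPI_passage``, ``evidence``, ``new_ppi`` and
    ``pairs`` (semicolon-separated ``mentionA|mentionB|trigger|rule``).
    Reading the output back yields documents structurally equal to the input.
    """
    annotations = annotations or {}
    for doc in documents:
        known = {s.index for s in doc.sentences()}
        for ann in annotations.get(doc.doc_id, []):
            missing = [i for i in ann.sentence_indices if i not in known]
            if missing:
                raise BioCValidationError(
                    f"annotation references unknown sentence index {missing[0]} "
                    f"in document {doc.doc_id}")

    root = etree.Element("collection")
    etree.SubElement(root, "source").text = source
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = "edgppi.key"
    ann_counter = 0
    for doc in documents:
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc.doc_id
        doc_anns = annotations.get(doc.doc_id, [])
        for section in doc.sections:
            pas_el = etree.SubElement(doc_el, "passage")
            inf = etree.SubElement(pas_el, "infon", key="section_type")
            inf.text = section.name + ("_title" if section.is_title else "")
            off_el = etree.SubElement(pas_el, "offset")
            off_el.text = str(section.sentences[0].offset if section.sentences else 0)
            sec_idx = {s.index for s in section.sentences}
            for sent in section.sentences:
                s_el = etree.SubElement(pas_el, "sentence")
                etree.SubElement(s_el, "offset").text = str(sent.offset)
                etree.SubElement(s_el, "text").text = sent.text
                for m in doc.mentions_in(sent):
                    a_el = etree.SubElement(s_el, "annotation", id=m.mention_id)
                    etree.SubElement(a_el, "infon", key="type").text = m.entity_type
                    etree.SubElement(a_el, "location",
                                     offset=str(m.start), length=str(m.end - m.start))
                    etree.SubElement(a_el, "text").text = m.text
            for ann in doc_anns:
                if ann.sentence_indices[0] not in sec_idx:
                    continue
                covered = [doc.sentence(i) for i in ann.sentence_indices]
                start = covered[0].offset
                end = covered[-1].end
                a_el = etree.SubElement(pas_el, "annotation", id=f"PPI{ann_counter}")
                ann_counter += 1
                etree.SubElement(a_el, "infon", key="type").text = "PPI_passage"
                etree.SubElement(a_el, "infon", key="evidence").text = ann.evidence
                etree.SubElement(a_el, "infon", key="new_ppi").text = str(ann.new_ppi).lower()
                etree.SubElement(a_el, "infon", key="pairs").text = ";".join(
                    f"{p.mention_a.mention_id}|{p.mention_b.mention_id}"
                    f"|{p.trigger_lemma}|{p.rule_id}"
                    for p in ann.pairs)
                etree.SubElement(a_el, "location", offset=str(start), length=str(end - start))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
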