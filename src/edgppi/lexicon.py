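"""Trigger lexicon: the lexical classes that license PPI extraction.

Five trigger classes drive the rules: PPI verbs (bind, interact, ...),
post-translational-modification verbs (acetylate, ...), relational noun
triggers (complex, dimer), indirect triggers (block, mediate) and process
triggers ("activity" plus ``-ion`` nominalizations of the PPI verbs,
generated automatically).  A sixth set holds the experimental-technique
keywords used by passage extension.  Only lemmas (base forms) are stored;
gerunds and nominalizations are mapped back to their base verb at match
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

DEFAULT_TECHNIQUE_KEYWORDS = ("2-hybrid", "bifc", "cosedimentation", "itc", "pulldown")

#: Nouns that name parts of a protein, used for part-whole detection.
DEFAULT_PART_NOUNS = ("domain", "region", "subunit", "motif", "site", "terminus",
                      "fragment", "cleft", "residue", "tail", "loop")

#: Sentence-initial phrases that mark experiment-goal statements.
DEFAULT_GOAL_PHRASES = ("to investigate", "to determine", "to test", "to examine")

_REQUIRED_KEYS = ("ppi_verbs", "ptm_verbs", "noun_triggers",
                  "indirect_triggers", "process_triggers")
_OPTIONAL_KEYS = ("technique_keywords", "part_nouns", "goal_phrases")


class LexiconConfigError(ValueError):
    pass


def ion_nominalization(verb: str) -> str | None:
    """The ``-ion`` nominalization of a verb, if one can be formed regularly
    (activate -> activation, interact -> interaction); None otherwise."""
    if verb.endswith("ate"):
        return verb[:-1] + "ion"
    if verb.endswith("t"):
        return verb + "ion"
    return None


def gerund(verb: str) -> str:
    """Regular -ing form (bind -> binding, associate -> associating)."""
    if verb.endswith("e") and not verb.endswith("ee"):
        return verb[:-1] + "ing"
    return verb + "ing"


@dataclass(frozen=True)
class TriggerLexicon:
    ppi_verbs: frozenset[str]
    ptm_verbs: frozenset[str]
    noun_triggers: frozenset[str]
    indirect_triggers: frozenset[str]
    process_triggers: frozenset[str]
    technique_keywords: tuple[str, ...] = DEFAULT_TECHNIQUE_KEYWORDS
    part_nouns: tuple[str, ...] = DEFAULT_PART_NOUNS
    goal_phrases: tuple[str, ...] = DEFAULT_GOAL_PHRASES
    #: lemma variant (gerund / -ion nominal) -> base verb, derived in __post_init__
    _base_of: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        base: dict[str, str] = {}
        for v in sorted(self.ppi_verbs | self.ptm_verbs):
            base.setdefault(v, v)
            base.setdefault(gerund(v), v)
            nom = ion_nominalization(v)
            if nom:
                base.setdefault(nom, v)
        object.__setattr__(self, "_base_of", base)

    # -- trigger-class tests (all take a lowercase lemma) -------------------

    def base_form(self, lemma: str) -> str:
        """Map a gerund/nominalization back to its base verb, else identity."""
        return self._base_of.get(lemma, lemma)

    def is_direct_trigger(self, lemma: str) -> bool:
        """PPI/PTM verb, or a gerund / -ion nominalization of one."""
        return self.base_form(lemma) in self.ppi_verbs or \
            self.base_form(lemma) in self.ptm_verbs

    def is_noun_trigger(self, lemma: str) -> bool:
        return lemma in self.noun_triggers

    def is_indirect_trigger(self, lemma: str) -> bool:
        return lemma in self.indirect_triggers

    def is_process_trigger(self, lemma: str) -> bool:
        return lemma in self.process_triggers

    def is_any_trigger(self, lemma: str) -> bool:
        return (self.is_direct_trigger(lemma) or self.is_noun_trigger(lemma)
                or self.is_indirect_trigger(lemma) or self.is_process_trigger(lemma))


def _as_set(value, key: str) -> frozenset[str]:
    if not isinstance(value, (list, tuple, set)):
        raise LexiconConfigError(f"lexicon key {key!r} must be a list of lemmas")
    return frozenset(str(v).lower() for v in value)


def load_lexicon(config_path=None) -> TriggerLexicon:
    """Load a trigger lexicon from a YAML config; with no path, load the
    shipped default.

    The config must define all five trigger sets (``ppi_verbs``,
    ``ptm_verbs``, ``noun_triggers``, ``indirect_triggers``,
    ``process_triggers``); ``technique_keywords``, ``part_nouns`` and
    ``goal_phrases`` are optional.  Process triggers are augmented with the
    regular ``-ion`` nominalizations of every PPI verb.
    """
    if config_path is None:
        text = resources.files("edgppi").joinpath("data/lexicon.yaml").read_text()
    else:
        with open(config_path, encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise LexiconConfigError("lexicon config must be a mapping; "
                                 f"all of {_REQUIRED_KEYS} are required")
    unknown = set(data) - set(_REQUIRED_KEYS) - set(_OPTIONAL_KEYS)
    if unknown:
        raise LexiconConfigError(f"unknown lexicon config keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise LexiconConfigError(f"lexicon config missing required keys: {missing}")

    ppi = _as_set(data["ppi_verbs"], "ppi_verbs")
    process = set(_as_set(data["process_triggers"], "process_triggers"))
    for v in ppi:
        nom = ion_nominalization(v)
        if nom:
            process.add(nom)
    kwargs = {}
    if "technique_keywords" in data:
        kwargs["technique_keywords"] = tuple(str(v).lower() for v in data["technique_keywords"])
    if "part_nouns" in data:
        kwargs["part_nouns"] = tuple(str(v).lower() for v in data["part_nouns"])
    if "goal_phrases" in data:
        kwargs["goal_phrases"] = tuple(str(v).lower() for v in data["goal_phrases"])
    return TriggerLexicon(
        ppi_verbs=ppi,
        ptm_verbs=_as_set(data["ptm_verbs"], "ptm_verbs"),
        noun_triggers=_as_set(data["noun_triggers"], "noun_triggers"),
        indirect_triggers=_as_set(data["indirect_triggers"], "indirect_triggers"),
        process_triggers=frozenset(process),
        **kwargs,
    )


@lru_cache(maxsize=1)
def default_lexicon() -> TriggerLexicon:
    return load_lexicon(None)
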