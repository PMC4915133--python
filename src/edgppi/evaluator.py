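"""Precision/recall/F scoring for pairs, sentences and passages.

All figures are percentages reported to one decimal, rounded half-up:
P = 100·TP/(TP+FP), R = 100·TP/(TP+FN), F = 2PR/(P+R), with 0/0 defined
as 0.  Pair scoring is unordered and document-level; sentence scoring is a
per-sentence binary comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .rule_engine import PPIPair, normalize_name


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_value: float


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def score_counts(c: ConfusionCounts) -> PRF:
    """Percent precision/recall/F from raw counts, one-decimal half-up."""
    p = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2.0 * p * r / (p + r) if p + r else 0.0
    return PRF(_round1(p), _round1(r), _round1(f))


def recall_only(tp: int, fn: int) -> float:
    """Recall percentage when false positives are not measurable (e.g.
    database-derived gold that marks only study-specific pairs)."""
    return score_counts(ConfusionCounts(tp, 0, fn)).recall


def score_pairs(predicted: list[PPIPair],
                gold: list[tuple[str, str]],
                aliases: dict[str, set[str]] | None = None) -> ConfusionCounts:
    """Unique-pair matching at document level.

    A predicted pair matches a gold ``(name_a, name_b)`` pair iff both
    normalized names match order-free; ``aliases`` (normalized name ->
    alternative normalized names, e.g. from document-wide abbreviation
    coreference) widen the match.
    """
    aliases = aliases or {}

    def expand(name: str) -> frozenset[str]:
        n = normalize_name(name)
        return frozenset({n} | set(aliases.get(n, ())))

    gold_keys = {frozenset({normalize_name(a), normalize_name(b)}) for a, b in gold}
    pred_expanded = []
    seen = set()
    for p in predicted:
        key = p.name_key
        if key in seen:
            continue
        seen.add(key)
        names = sorted(key)
        pred_expanded.append((key, [expand(n) for n in names]))

    matched_gold: set[frozenset[str]] = set()
    tp = 0
    for key, expansions in pred_expanded:
        hit = None
        for g in gold_keys - matched_gold:
            gnames = sorted(g)
            if len(gnames) != len(expansions):
                continue
            ga, gb = (gnames + [""])[:2] if len(gnames) == 2 else (gnames[0], gnames[0])
            ea, eb = expansions if len(expansions) == 2 else (expansions[0], expansions[0])
            if (ga in ea and gb in eb) or (ga in eb and gb in ea):
                hit = g
                break
        if hit is not None:
            matched_gold.add(hit)
            tp += 1
    fp = len(pred_expanded) - tp
    fn = len(gold_keys) - len(matched_gold)
    return ConfusionCounts(tp, fp, fn)


def score_sentences(predicted: dict[str, set[int]],
                    gold: dict[str, set[int]]) -> ConfusionCounts:
    """Per-sentence binary comparison summed over documents."""
    tp = fp = fn = 0
    for doc_id in sorted(set(predicted) | set(gold)):
        p = predicted.get(doc_id, set())
        g = gold.get(doc_id, set())
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    return ConfusionCounts(tp, fp, fn)


# ---------------------------------------------------------------------------
# Gold-file I/O and reporting


def read_gold_pairs(path) -> dict[str, list[tuple[str, str]]]:
    """TSV ``doc_id<TAB>name_a<TAB>name_b`` -> per-document gold pairs."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            doc_id, a, b = line.split("\t")[:3]
            out.setdefault(doc_id, []).append((a, b))
    return out


def read_gold_sentences(path) -> dict[str, set[int]]:
    """TSV ``doc_id<TAB>sentence_index`` -> per-document gold sentence sets."""
    out: dict[str, set[int]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            doc_id, idx = line.split("\t")[:2]
            out.setdefault(doc_id, set()).add(int(idx))
    return out


def format_report(rows: list[tuple[str, ConfusionCounts]]) -> str:
    """Pretty table of labeled confusion rows with their P/R/F."""
    header = f"{'task':<24}{'TP':>6}{'FP':>6}{'FN':>6}{'Prec.':>8}{'Recall':>8}{'F':>8}"
    lines = [header, "-" * len(header)]
    for label, c in rows:
        prf = score_counts(c)
        lines.append(f"{label:<24}{c.tp:>6}{c.fp:>6}{c.fn:>6}"
                     f"{prf.precision:>8.1f}{prf.recall:>8.1f}{prf.f_value:>8.1f}")
    return "\n".join(lines)
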