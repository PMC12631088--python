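"""Scoring for span extraction and normalization.

Implements the task's evaluation regimes:

* **exact** span matching — predicted fragment offsets must be identical to
  a gold mention's;
* **partial** span matching — the prediction must share at least one whole
  token (maximal non-whitespace run) with a gold mention;
* **normalization-only** — scored purely on HPO identifiers of key
  findings, spans ignored;
* **combined** — span match (exact or partial) *and* identifier equality;
* **disjoint-only** stratification — restricted to discontinuous mentions;
* **class-wise** — restricted to one label (KEYF or NORMF);
* overlap-structure categorization of discontinuous mentions (no / left /
  right / multiple overlap with sibling mentions);
* corpus statistics (entity, disjoint and label counts, percent disjoint).

Matching is one-to-one and greedy by descending shared-character count
(ties broken by gold offset order), which makes exact-mode true positives
a subset of partial-mode ones. Precision is TP/(TP+FP), recall
TP/(TP+FN), and F1 the harmonic mean 2PR/(P+R); degenerate denominators
score 0.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from ._tokens import token_spans
from .corpus import KEYF, AnnotatedObservation, Mention
from .exceptions import ValidationError

__all__ = [
    "Mode",
    "ConfusionCounts",
    "EvalReport",
    "DiscCategory",
    "prf",
    "match_spans",
    "match_corpus",
    "evaluate_spans",
    "evaluate_normalization",
    "evaluate_combined",
    "disjoint_only",
    "categorize_disc",
    "classwise",
    "CorpusStats",
    "corpus_stats",
    "percent_disjoint",
    "format_report_rows",
]

Mode = Literal["exact", "partial"]
_MODES = ("exact", "partial")


@dataclass(frozen=True)
class ConfusionCounts:
    """True-positive / false-positive / false-negative tallies."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class EvalReport:
    """Precision/recall/F1 with the confusion counts they derive from."""

    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float

    def row(self) -> tuple[float, float, float]:
        return (self.precision, self.recall, self.f1)


def prf(counts: ConfusionCounts) -> EvalReport:
    """Precision, recall and harmonic-mean F1 from confusion counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(counts, precision, recall, f1)


def _covered_tokens(text: str, mention: Mention) -> frozenset[tuple[int, int]]:
    """Whole text tokens (by span) fully covered by some fragment of the mention."""
    out = set()
    for ts, te in token_spans(text):
        for f in mention.fragments:
            if f.start <= ts and te <= f.end:
                out.add((ts, te))
                break
    return frozenset(out)


def _shared_chars(a: Mention, b: Mention) -> int:
    total = 0
    for fa in a.fragments:
        for fb in b.fragments:
            total += max(0, min(fa.end, fb.end) - max(fa.start, fb.start))
    return total


def _greedy_pairs(
    gold: Sequence[Mention],
    pred: Sequence[Mention],
    matches: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """One-to-one assignment: descending shared characters, ties by gold offset order."""
    ranked = sorted(
        matches,
        key=lambda gp: (
            -_shared_chars(gold[gp[0]], pred[gp[1]]),
            gold[gp[0]].start,
            gold[gp[0]].end,
            gp[0],
            gp[1],
        ),
    )
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for g, p in ranked:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        pairs.append((g, p))
    return pairs


def _span_match(
    text: str, gold: Mention, pred: Mention, mode: Mode,
    token_cache: dict[int, frozenset[tuple[int, int]]],
) -> bool:
    if mode == "exact":
        return gold.fragments == pred.fragments
    gk, pk = id(gold), id(pred)
    if gk not in token_cache:
        token_cache[gk] = _covered_tokens(text, gold)
    if pk not in token_cache:
        token_cache[pk] = _covered_tokens(text, pred)
    return bool(token_cache[gk] & token_cache[pk])


def match_spans(
    gold: Sequence[Mention],
    pred: Sequence[Mention],
    mode: Mode,
    text: str,
    *,
    require_id_match: bool = False,
) -> ConfusionCounts:
    """Confusion counts for one observation's gold vs predicted mentions.

    ``require_id_match=True`` additionally demands equal ``hpo_id`` on a
    matched pair (the combined regime); two absent ids compare equal.
    """
    if mode not in _MODES:
        raise ValidationError(f"unknown matching mode {mode!r}")
    cache: dict[int, frozenset[tuple[int, int]]] = {}
    matches = {
        (g, p)
        for g, gm in enumerate(gold)
        for p, pm in enumerate(pred)
        if _span_match(text, gm, pm, mode, cache)
        and (not require_id_match or gm.hpo_id == pm.hpo_id)
    }
    tp = len(_greedy_pairs(gold, pred, matches))
    return ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def _paired(
    gold: Sequence[AnnotatedObservation], pred: Sequence[AnnotatedObservation]
) -> list[tuple[str, str, list[Mention], list[Mention]]]:
    """Align two corpora by observation id; absent sides contribute empty mention lists."""
    gold_by_id = {a.id: a for a in gold}
    pred_by_id = {a.id: a for a in pred}
    for oid in gold_by_id.keys() & pred_by_id.keys():
        if gold_by_id[oid].text != pred_by_id[oid].text:
            raise ValidationError(f"observation {oid!r} has different text in gold and pred")
    out = []
    for oid, ann in gold_by_id.items():
        p = pred_by_id.get(oid)
        out.append((oid, ann.text, list(ann.mentions), list(p.mentions) if p else []))
    for oid, ann in pred_by_id.items():
        if oid not in gold_by_id:
            out.append((oid, ann.text, [], list(ann.mentions)))
    return out


def match_corpus(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
    mode: Mode,
    *,
    require_id_match: bool = False,
    label: str | None = None,
) -> ConfusionCounts:
    """Sum per-observation span-matching counts over aligned corpora."""
    total = ConfusionCounts()
    for _, text, g, p in _paired(gold, pred):
        if label is not None:
            g = [m for m in g if m.label == label]
            p = [m for m in p if m.label == label]
        total = total + match_spans(g, p, mode, text, require_id_match=require_id_match)
    return total


def evaluate_spans(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
    mode: Mode,
) -> EvalReport:
    """Span-extraction score (identifiers ignored)."""
    return prf(match_corpus(gold, pred, mode))


def evaluate_normalization(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
) -> EvalReport:
    """Normalization-only score: multiset intersection of KEYF HPO ids per observation.

    Spans are ignored entirely. Key findings lacking an id cannot match
    anything: they still count toward the denominator (gold side as false
    negatives, predicted side as false positives).
    """
    counts = ConfusionCounts()
    for _, _, g, p in _paired(gold, pred):
        g_ids = Counter(m.hpo_id for m in g if m.label == KEYF and m.hpo_id)
        p_ids = Counter(m.hpo_id for m in p if m.label == KEYF and m.hpo_id)
        g_missing = sum(1 for m in g if m.label == KEYF and not m.hpo_id)
        p_missing = sum(1 for m in p if m.label == KEYF and not m.hpo_id)
        tp = sum((g_ids & p_ids).values())
        counts = counts + ConfusionCounts(
            tp=tp,
            fp=sum(p_ids.values()) - tp + p_missing,
            fn=sum(g_ids.values()) - tp + g_missing,
        )
    return prf(counts)


def evaluate_combined(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
    mode: Mode,
) -> EvalReport:
    """Combined extraction + normalization: span match under ``mode`` AND equal ids."""
    return prf(match_corpus(gold, pred, mode, require_id_match=True))


def disjoint_only(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
    mode: Mode,
) -> EvalReport:
    """Score restricted to discontinuous mentions.

    Gold is restricted to mentions with >=2 fragments. Every prediction may
    still match a retained gold (so a contiguous prediction can, in partial
    mode, hit a disjoint gold), but unmatched predictions only count as
    false positives when they are themselves discontinuous.
    """
    counts = ConfusionCounts()
    for _, text, g, p in _paired(gold, pred):
        g_disc = [m for m in g if m.is_disjoint]
        cache: dict[int, frozenset[tuple[int, int]]] = {}
        matches = {
            (gi, pi)
            for gi, gm in enumerate(g_disc)
            for pi, pm in enumerate(p)
            if _span_match(text, gm, pm, mode, cache)
        }
        pairs = _greedy_pairs(g_disc, p, matches)
        matched_p = {pi for _, pi in pairs}
        fp = sum(1 for pi, pm in enumerate(p) if pi not in matched_p and pm.is_disjoint)
        counts = counts + ConfusionCounts(tp=len(pairs), fp=fp, fn=len(g_disc) - len(pairs))
    return prf(counts)


class DiscCategory(enum.Enum):
    """Structural category of a discontinuous mention relative to its siblings."""

    CONTIGUOUS = "contiguous"
    NO_OVERLAP = "no_overlap"
    LEFT_OVERLAP = "left_overlap"
    RIGHT_OVERLAP = "right_overlap"
    MULTIPLE_OVERLAP = "multiple_overlap"


def categorize_disc(
    text: str, mention: Mention, siblings: Sequence[Mention]
) -> DiscCategory:
    """Classify a discontinuous mention's token sharing with sibling mentions.

    A single-fragment mention is ``CONTIGUOUS``. Otherwise: no shared token
    with any sibling -> ``NO_OVERLAP``; shared tokens forming one
    consecutive region located in the leftmost / rightmost fragment ->
    ``LEFT_OVERLAP`` / ``RIGHT_OVERLAP``; shared regions at more than one
    position, a region confined to a middle fragment, or sharing with two
    or more siblings -> ``MULTIPLE_OVERLAP``.
    """
    if len(mention.fragments) == 1:
        return DiscCategory.CONTIGUOUS
    own = _covered_tokens(text, mention)
    sharers = []
    shared: set[tuple[int, int]] = set()
    for sib in siblings:
        if sib is mention or sib.fragments == mention.fragments:
            continue
        common = own & _covered_tokens(text, sib)
        if common:
            sharers.append(sib)
            shared |= common
    if not sharers:
        return DiscCategory.NO_OVERLAP
    if len(sharers) >= 2:
        return DiscCategory.MULTIPLE_OVERLAP
    ordered = sorted(own)
    flags = [t in shared for t in ordered]
    regions = 0
    prev = False
    for f in flags:
        if f and not prev:
            regions += 1
        prev = f
    if regions > 1:
        return DiscCategory.MULTIPLE_OVERLAP
    first, last = mention.fragments[0], mention.fragments[-1]
    if all(first.start <= ts and te <= first.end for ts, te in shared):
        return DiscCategory.LEFT_OVERLAP
    if all(last.start <= ts and te <= last.end for ts, te in shared):
        return DiscCategory.RIGHT_OVERLAP
    return DiscCategory.MULTIPLE_OVERLAP


def classwise(
    gold: Sequence[AnnotatedObservation],
    pred: Sequence[AnnotatedObservation],
    mode: Mode,
    label: str,
) -> EvalReport:
    """Span score with both corpora restricted to one label before matching."""
    return prf(match_corpus(gold, pred, mode, label=label))


def percent_disjoint(n_disjoint: int, n_entities: int) -> float:
    """Percent of discontinuous mentions among all entities, to one decimal."""
    if n_entities == 0:
        return 0.0
    return round(100.0 * n_disjoint / n_entities, 1)


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-level structural counts."""

    n_observations: int
    n_entities: int
    n_disjoint: int
    pct_disjoint: float
    n_disjoint_2part: int
    n_disjoint_3part: int
    n_normf: int
    n_keyf: int


def corpus_stats(corpus: Sequence[AnnotatedObservation]) -> CorpusStats:
    """Observation/entity/disjoint/label tallies for an annotated corpus."""
    n_entities = n_disjoint = n_2 = n_3 = n_normf = 0
    for ann in corpus:
        for m in ann.mentions:
            n_entities += 1
            if m.label != KEYF:
                n_normf += 1
            if m.is_disjoint:
                n_disjoint += 1
                if len(m.fragments) == 2:
                    n_2 += 1
                else:
                    n_3 += 1
    return CorpusStats(
        n_observations=len(corpus),
        n_entities=n_entities,
        n_disjoint=n_disjoint,
        pct_disjoint=percent_disjoint(n_disjoint, n_entities),
        n_disjoint_2part=n_2,
        n_disjoint_3part=n_3,
        n_normf=n_normf,
        n_keyf=n_entities - n_normf,
    )


def format_report_rows(rows: Iterable[tuple[str, str, EvalReport]]) -> str:
    """Tab-separated report: one line per (stratum, mode) with P/R/F1 to 3 decimals."""
    lines = ["stratum\tmode\tprecision\trecall\tf1\ttp\tfp\tfn"]
    for stratum, mode, report in rows:
        c = report.counts
        lines.append(
            f"{stratum}\t{mode}\t{report.precision:.3f}\t{report.recall:.3f}"
            f"\t{report.f1:.3f}\t{c.tp}\t{c.fp}\t{c.fn}"
        )
    return "\n".join(lines) + "\n"
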