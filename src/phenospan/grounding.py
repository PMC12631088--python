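"""Offset recovery ("grounding") for generated mention surfaces.

A seq2seq NER backend emits mention text without offsets; scoring and
downstream use require character spans, so each decoded surface must be
located in the observation text — including discontinuous placements where
the surface tokens appear as up to three separated runs.

Search procedure for one surface:

1. If the surface occurs contiguously, return the leftmost contiguous
   occurrence as a single fragment.
2. Otherwise align whitespace tokens: partition the surface tokens into at
   most ``max_fragments`` contiguous runs, each run matching a contiguous
   run of text tokens, runs strictly left-to-right with at least one text
   token between them. Among feasible placements, the one minimizing
   (fragment count, then fragment start offsets lexicographically) wins —
   contiguous readings are preferred, then leftmost.
3. The whole search is case-sensitive first, with a case-insensitive
   fallback pass. Token comparison additionally strips edge punctuation
   from the text token when exact equality fails, so "hooding" matches
   the text token "hooding.", tight to the stripped core.

An infeasible surface yields ``None`` (an "ungrounded" value, not an
exception): the caller decides whether to drop or report it.
"""

from __future__ import annotations

from .corpus import Mention, Observation, SpanFragment
from ._tokens import strip_punct_span, token_spans
from .codec import DecodedMention
from .exceptions import ValidationError

__all__ = ["ground_surface", "ground_all"]


def _match_token(
    text: str, span: tuple[int, int], wanted: str, casefold: bool
) -> tuple[int, int] | None:
    """Span of ``wanted`` within the text token at ``span``, or None.

    Exact token equality matches the full token; otherwise the token with
    edge punctuation stripped is compared, and on success the stripped core
    span is returned (fragments stay tight to what was matched).
    """
    raw = text[span[0] : span[1]]
    if casefold:
        raw, wanted = raw.casefold(), wanted.casefold()
    if raw == wanted:
        return span
    cs, ce = strip_punct_span(text, *span)
    if cs < ce:
        core = text[cs:ce]
        if (core.casefold() if casefold else core) == wanted:
            return (cs, ce)
    return None


def _compositions(total: int, parts: int) -> list[tuple[int, ...]]:
    """All ways to write ``total`` as ``parts`` positive integers, in order."""
    if parts == 1:
        return [(total,)]
    out = []
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return out


def _place_runs(
    text: str,
    tspans: list[tuple[int, int]],
    stoks: list[str],
    run_lengths: tuple[int, ...],
    casefold: bool,
) -> list[SpanFragment] | None:
    """Lexicographically earliest placement of the given surface-token runs.

    Depth-first over text positions in ascending order: the first complete
    placement found has the minimal tuple of fragment start offsets.
    """
    n = len(tspans)

    def match_run(tok_idx: int, start: int, length: int) -> tuple[int, int] | None:
        # Match stoks[start:start+length] against text tokens tok_idx.. ; return char span.
        first = last = None
        for j in range(length):
            got = _match_token(text, tspans[tok_idx + j], stoks[start + j], casefold)
            if got is None:
                return None
            if j == 0:
                first = got[0]
            last = got[1]
        assert first is not None and last is not None
        return first, last

    def rec(run_no: int, stok_pos: int, min_tok: int) -> list[SpanFragment] | None:
        if run_no == len(run_lengths):
            return []
        length = run_lengths[run_no]
        remaining = sum(run_lengths[run_no + 1 :])
        # Leave room for later runs plus one gap token before each.
        for tok_idx in range(min_tok, n - length - remaining + 1 - (len(run_lengths) - run_no - 1)):
            span = match_run(tok_idx, stok_pos, length)
            if span is None:
                continue
            tail = rec(run_no + 1, stok_pos + length, tok_idx + length + 1)
            if tail is not None:
                return [SpanFragment(*span)] + tail
        return None

    return rec(0, 0, 0)


def ground_surface(
    text: str, surface: str, max_fragments: int = 3
) -> list[SpanFragment] | None:
    """Locate ``surface`` in ``text`` as 1..max_fragments fragments, or ``None``.

    See the module docstring for the search order and objective.
    """
    surface = surface.strip()
    if not surface:
        raise ValidationError("cannot ground an empty surface")
    stoks = surface.split()
    for casefold in (False, True):
        haystack, needle = (text.casefold(), surface.casefold()) if casefold else (text, surface)
        idx = haystack.find(needle)
        if idx >= 0:
            return [SpanFragment(idx, idx + len(needle))]
        tspans = token_spans(text)
        for n_frag in range(1, max_fragments + 1):
            best: list[SpanFragment] | None = None
            for comp in _compositions(len(stoks), n_frag) if n_frag <= len(stoks) else []:
                placed = _place_runs(text, tspans, stoks, comp, casefold)
                if placed is None:
                    continue
                if best is None or [f.start for f in placed] < [f.start for f in best]:
                    best = placed
            if best is not None:
                return best
    return None


def ground_all(
    observation: Observation,
    decoded: list[DecodedMention],
    max_fragments: int = 3,
) -> tuple[list[Mention], list[DecodedMention]]:
    """Ground every decoded mention independently against one observation.

    Returns ``(mentions, ungrounded)``: grounded mentions carry their label
    and no HPO id yet; duplicates by (label, fragments) are collapsed; the
    surfaces that could not be placed are returned separately so callers can
    log them (dropped predictions still cost precision and must be visible).
    """
    mentions: list[Mention] = []
    ungrounded: list[DecodedMention] = []
    seen: set[tuple[str, tuple[SpanFragment, ...]]] = set()
    for dec in decoded:
        fragments = ground_surface(observation.text, dec.surface, max_fragments)
        if fragments is None:
            ungrounded.append(dec)
            continue
        key = (dec.label, tuple(fragments))
        if key in seen:
            continue
        seen.add(key)
        mentions.append(Mention(dec.label, tuple(fragments)))
    return mentions, ungrounded
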