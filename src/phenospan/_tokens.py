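"""Whitespace tokenization with character offsets.

Tokens are maximal non-whitespace runs; punctuation stays attached to its
token. Several modules (grounding, partial-match evaluation, the stub
backend) need the same offset-preserving view of a text, so it lives here.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"\S+")

# Characters treated as strippable token-edge punctuation.
_PUNCT = ".,;:!?()[]{}'\"`"


def token_spans(text: str) -> list[tuple[int, int]]:
    """Half-open [start, end) character spans of whitespace tokens, left to right."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def strip_punct_span(text: str, start: int, end: int) -> tuple[int, int]:
    """Shrink a token span by stripping edge punctuation; may become empty (start == end)."""
    while start < end and text[start] in _PUNCT:
        start += 1
    while end > start and text[end - 1] in _PUNCT:
        end -= 1
    return start, end
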