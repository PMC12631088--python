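"""Linearization codec for sequence-to-sequence NER.

A generative NER backend consumes the raw observation text and emits a
single target string listing the recognized mentions, each prefixed with
its label and separated by semicolons::

    KEYF: Excess nuchal skin; NORMF: NECK: no webbing; NORMF: NECK: no cysts

No special markup distinguishes discontinuous mentions: their surface is
simply the fragment substrings joined by spaces, and offset recovery is
deferred to the grounding stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus import KEYF, NORMF, AnnotatedObservation, mention_surface
from .exceptions import ValidationError

__all__ = ["DecodedMention", "encode_target", "decode_target", "SEGMENT_SEPARATOR"]

logger = logging.getLogger(__name__)

SEGMENT_SEPARATOR = "; "

_SEGMENT_RE = re.compile(r"^\s*(KEYF|NORMF)\s*:\s*(.*)$", re.DOTALL)


@dataclass(frozen=True)
class DecodedMention:
    """(label, surface) pair parsed from a generated target, before grounding."""

    label: str
    surface: str

    def __post_init__(self) -> None:
        if self.label not in (KEYF, NORMF):
            raise ValidationError(f"unknown label {self.label!r}")
        if not self.surface or self.surface != self.surface.strip():
            raise ValidationError("surface must be non-empty and stripped")


def encode_target(annotated: AnnotatedObservation) -> str:
    """Serialize gold mentions into the training target string.

    Segments are ``"<LABEL>: <surface>"`` joined by ``"; "``. Ordering is
    deterministic so identical corpora yield identical training targets:
    KEYF segments first, then NORMF; within a label by the tuple of fragment
    start offsets (shared-head mentions tie on the first fragment and are
    resolved by where they diverge), ties by surface. A mention-less
    observation encodes to ``""``.
    """
    text = annotated.text
    keyed = []
    for m in annotated.mentions:
        surface = mention_surface(text, m.fragments)
        if SEGMENT_SEPARATOR.strip() in surface:
            # A surface containing the separator cannot round-trip; flag it.
            logger.warning(
                "surface %r in observation %s contains the segment separator",
                surface, annotated.id,
            )
        starts = tuple(f.start for f in m.fragments)
        keyed.append(((0 if m.label == KEYF else 1, starts, surface), m.label, surface))
    keyed.sort(key=lambda item: item[0])
    return SEGMENT_SEPARATOR.join(f"{label}: {surface}" for _, label, surface in keyed)


def decode_target(target: str, *, warnings: list[str] | None = None) -> list[DecodedMention]:
    """Parse a generated target string into decoded mentions.

    Model output is untrusted: segments are split on ``";"``, each must open
    with a ``KEYF:`` or ``NORMF:`` prefix (only the first colon delimits the
    label, so surfaces like ``"NECK: no webbing"`` survive intact), and
    surfaces are stripped. Unrecognized segments are never fatal — they are
    skipped, logged, and appended to ``warnings`` when a list is supplied.
    Duplicate (label, surface) pairs are collapsed keeping the first.
    """
    out: list[DecodedMention] = []
    seen: set[tuple[str, str]] = set()
    for segment in target.split(";"):
        if not segment.strip():
            continue
        m = _SEGMENT_RE.match(segment)
        surface = m.group(2).strip() if m else ""
        if not m or not surface:
            msg = f"segment without a recognized label prefix skipped: {segment.strip()!r}"
            logger.warning(msg)
            if warnings is not None:
                warnings.append(msg)
            continue
        key = (m.group(1), surface)
        if key in seen:
            continue
        seen.add(key)
        out.append(DecodedMention(*key))
    return out
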