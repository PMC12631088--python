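"""Standoff annotation model and tab-separated corpus I/O.

A corpus is a set of clinical observations, each carrying zero or more
phenotype mentions. A mention is a labeled set of 1-3 character-offset
fragments over the observation text: a single fragment for an ordinary
(continuous) mention, 2-3 fragments for a discontinuous ("disjoint")
mention whose tokens are interrupted by unrelated words. Offsets are
0-based, half-open ``[start, end)``.

Two labels exist:

* ``KEYF`` -- key finding: a phenotypic abnormality is present; these are
  the mentions normalized to HPO identifiers.
* ``NORMF`` -- normal finding: absence of an abnormality ("intact palate");
  excluded from normalization.

The on-disk format is a 5-column tab-separated file: observation ID,
observation text, HPO identifier, polarity ("X" for normal findings, "NA"
for key findings) and the span field. A discontinuous span is written as
comma-separated ranges, e.g. ``17-27,37-42``.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .exceptions import FormatError, ValidationError

__all__ = [
    "KEYF",
    "NORMF",
    "LABELS",
    "SpanFragment",
    "Mention",
    "Observation",
    "AnnotatedObservation",
    "parse_span_field",
    "format_span_field",
    "mention_surface",
    "read_annotations",
    "write_predictions",
]

logger = logging.getLogger(__name__)

KEYF = "KEYF"
NORMF = "NORMF"
LABELS = (KEYF, NORMF)

#: Polarity cell values accepted on read, per label written back.
_POLARITY_TO_LABEL = {"X": NORMF, "NA": KEYF, "N/A": KEYF}
_LABEL_TO_POLARITY = {NORMF: "X", KEYF: "NA"}

HPO_ID_RE = re.compile(r"^HP:\d{7}$")

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")

HEADER = ("observation_id", "text", "hpo_id", "polarity", "spans")

MAX_FRAGMENTS = 3


@dataclass(frozen=True, order=True)
class SpanFragment:
    """Half-open character range [start, end), 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid fragment ({self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _check_fragments(fragments: tuple[SpanFragment, ...]) -> None:
    if not 1 <= len(fragments) <= MAX_FRAGMENTS:
        raise ValidationError(
            f"mention must have 1-{MAX_FRAGMENTS} fragments, got {len(fragments)}"
        )
    for prev, cur in zip(fragments, fragments[1:]):
        if cur.start <= prev.end:
            # Covers overlap (cur.start < prev.end) and adjacency (==): consecutive
            # fragments must be separated by at least one character.
            raise ValidationError(
                f"fragments {prev} and {cur} overlap, touch, or are out of order"
            )


@dataclass(frozen=True)
class Mention:
    """A labeled phenotype mention: 1-3 ordered, disjoint, non-adjacent fragments.

    ``hpo_id`` is the normalized ontology identifier ("HP:" + 7 digits) when
    known, else ``None``.
    """

    label: str
    fragments: tuple[SpanFragment, ...]
    hpo_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown mention label {self.label!r}")
        object.__setattr__(self, "fragments", tuple(self.fragments))
        _check_fragments(self.fragments)

    @property
    def is_disjoint(self) -> bool:
        return len(self.fragments) > 1

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def end(self) -> int:
        return self.fragments[-1].end


@dataclass(frozen=True)
class Observation:
    """One clinical observation: an opaque ID and its raw text."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("observation id must be non-empty")
        if not self.text:
            raise ValidationError("observation text must be non-empty")


@dataclass
class AnnotatedObservation:
    """An observation together with its gold or predicted mentions.

    Mentions may overlap one another (shared heads from coordination
    ellipsis), but each mention must individually fit the text.
    """

    observation: Observation
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.mentions:
            if m.end > len(self.observation.text):
                raise ValidationError(
                    f"mention {m.fragments} exceeds text bounds of observation "
                    f"{self.observation.id!r} (length {len(self.observation.text)})"
                )

    @property
    def id(self) -> str:
        return self.observation.id

    @property
    def text(self) -> str:
        return self.observation.text


def parse_span_field(field_text: str) -> list[SpanFragment]:
    """Parse a span field like ``"17-27,37-42"`` into sorted fragments.

    Accepts optional spaces around the comma. Raises :class:`FormatError`
    naming the offending token for malformed ranges, empty fields, more than
    3 ranges, or ranges that overlap or touch.
    """
    if not field_text.strip():
        raise FormatError("empty span field")
    parts = [p.strip() for p in field_text.split(",")]
    fragments = []
    for part in parts:
        m = _RANGE_RE.match(part)
        if not m:
            raise FormatError(f"malformed span range {part!r} in field {field_text!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if start >= end:
            raise FormatError(f"empty or inverted span range {part!r}")
        fragments.append(SpanFragment(start, end))
    fragments.sort()
    if len(fragments) > MAX_FRAGMENTS:
        raise FormatError(
            f"span field {field_text!r} has {len(fragments)} ranges (max {MAX_FRAGMENTS})"
        )
    try:
        _check_fragments(tuple(fragments))
    except ValidationError as exc:
        raise FormatError(f"invalid span field {field_text!r}: {exc}") from exc
    return fragments


def format_span_field(fragments: Iterable[SpanFragment]) -> str:
    """Inverse of :func:`parse_span_field`: ``[(17,27),(37,42)] -> "17-27,37-42"``."""
    fragments = tuple(fragments)
    _check_fragments(fragments)
    return ",".join(f"{f.start}-{f.end}" for f in fragments)


def mention_surface(text: str, fragments: Iterable[SpanFragment]) -> str:
    """Surface string of a mention: fragment substrings joined by single spaces."""
    out = []
    for f in fragments:
        if f.end > len(text):
            raise ValidationError(f"fragment {f} out of bounds for text of length {len(text)}")
        out.append(text[f.start : f.end])
    return " ".join(out)


def _is_header_row(cells: list[str]) -> bool:
    # A header is recognized by its span cell: non-empty but not parseable as
    # offset ranges (data rows have either valid ranges or, for mention-less
    # decoy observations, an empty field).
    spans = cells[4].strip()
    if not spans:
        return False
    try:
        parse_span_field(spans)
    except FormatError:
        return True
    return False


StreamOrPath = Union[str, Path, IO[str], Iterable[str]]


def _iter_lines(source: StreamOrPath) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_annotations(source: StreamOrPath, *, strict: bool = True) -> list[AnnotatedObservation]:
    """Read a 5-column tab-separated annotation file into annotated observations.

    Rows are grouped by observation ID preserving first-seen order. Polarity
    "X" maps to NORMF, "NA"/"N/A" to KEYF; the HPO cell is kept verbatim for
    both labels (a warning is logged when it does not look like an HPO id).
    Rows whose HPO, polarity and span cells are all empty register a
    mention-less observation.

    With ``strict=True`` (default) any invalid row raises :class:`FormatError`
    carrying its 1-based row number; with ``strict=False`` such rows are
    logged and skipped — real corpora contain occasional offset
    inconsistencies and a lenient pass is often the pragmatic choice.
    """
    by_id: dict[str, AnnotatedObservation] = {}
    for row_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 5:
            msg = f"row {row_no}: expected 5 tab-separated columns, got {len(cells)}"
            if strict:
                raise FormatError(msg)
            logger.warning("%s (skipped)", msg)
            continue
        if row_no == 1 and _is_header_row(cells):
            continue
        obs_id, text, hpo, polarity, spans = (c.strip() for c in cells)
        try:
            obs = Observation(obs_id, text)
            if obs_id in by_id and by_id[obs_id].text != text:
                raise FormatError(
                    f"row {row_no}: observation {obs_id!r} repeated with different text"
                )
            record = by_id.setdefault(obs_id, AnnotatedObservation(obs))
            if not hpo and not polarity and not spans:
                continue  # mention-less observation row
            polarity_key = polarity.upper()
            if polarity_key not in _POLARITY_TO_LABEL:
                raise FormatError(f"row {row_no}: unknown polarity value {polarity!r}")
            label = _POLARITY_TO_LABEL[polarity_key]
            hpo_id = hpo or None
            if hpo_id is not None and not HPO_ID_RE.match(hpo_id):
                logger.warning(
                    "row %d: HPO identifier %r does not match the HP:NNNNNNN pattern "
                    "(kept verbatim)", row_no, hpo_id,
                )
            fragments = tuple(parse_span_field(spans))
            mention = Mention(label, fragments, hpo_id)
            if mention.end > len(text):
                raise ValidationError(
                    f"row {row_no}: span {spans!r} exceeds text of length {len(text)}"
                )
            record.mentions.append(mention)
        except (FormatError, ValidationError) as exc:
            if strict:
                if "row" in str(exc):
                    raise
                raise FormatError(f"row {row_no}: {exc}") from exc
            logger.warning("row %d skipped: %s", row_no, exc)
    return list(by_id.values())


def write_predictions(
    target: Union[str, Path, IO[str]],
    records: Iterable[AnnotatedObservation],
    *,
    header: bool = True,
) -> None:
    """Write annotated observations back to the 5-column tab-separated format.

    One row per mention (mention-less observations get a single row with the
    last three columns empty); UTF-8, LF line endings. Inverse of
    :func:`read_annotations`.
    """
    own = isinstance(target, (str, Path))
    fh: IO[str] = open(target, "w", encoding="utf-8", newline="\n") if own else target  # type: ignore[arg-type]
    try:
        if header:
            fh.write("\t".join(HEADER) + "\n")
        for rec in records:
            if not rec.mentions:
                fh.write(f"{rec.id}\t{rec.text}\t\t\t\n")
                continue
            for m in rec.mentions:
                fh.write(
                    "\t".join(
                        (
                            rec.id,
                            rec.text,
                            m.hpo_id or "",
                            _LABEL_TO_POLARITY[m.label],
                            format_span_field(m.fragments),
                        )
                    )
                    + "\n"
                )
    finally:
        if own:
            fh.close()


def annotations_to_string(records: Iterable[AnnotatedObservation], *, header: bool = True) -> str:
    """Convenience: :func:`write_predictions` into a string."""
    buf = io.StringIO()
    write_predictions(buf, records, header=header)
    return buf.getvalue()
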