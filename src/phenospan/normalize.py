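"""Normalization of extracted key findings to HPO identifiers.

The normalizer follows a retrieve-then-rerank architecture:

1. **Candidate generation.** Every dictionary surface (preferred terms and
   synonyms as separate rows) is embedded once into a unit-norm vector; a
   query surface is embedded the same way and scored against all rows by
   cosine similarity; the top ``k`` (default 30) surfaces are retained.
2. **Reranking.** A pair scorer reads each (mention surface, candidate
   term) combination and rescores it; candidates are re-sorted and the
   top-scoring candidate's identifier is the normalization result.

Production systems back both stages with trained sentence encoders and
cross-encoders. The reference components here — a hashing character-n-gram
encoder and a token-set Dice reranker — are deterministic and
dependency-free while preserving the architecture exactly, so retrieval
behavior (ranking, ties, truncation, top-1 selection) is testable at desk
scale. Real models plug in through the same two contracts.

The dictionary can be augmented with (surface, id) synonym pairs harvested
from an annotated training corpus, which measurably helps retrieval of
corpus-specific phrasings.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Protocol, Sequence, Union, runtime_checkable

import numpy as np

from .corpus import KEYF, HPO_ID_RE, AnnotatedObservation, mention_surface
from .exceptions import FormatError, ValidationError

__all__ = [
    "OntologyEntry",
    "OntologyDictionary",
    "Candidate",
    "EncoderContract",
    "RerankerContract",
    "load_dictionary",
    "augment_dictionary",
    "HashingNgramEncoder",
    "reference_encoder",
    "DiceReranker",
    "reference_reranker",
    "EmbeddingIndex",
    "build_index",
    "generate_candidates",
    "rerank",
    "normalize_mention",
    "Normalizer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OntologyEntry:
    """One dictionary row: a surface term for an HPO identifier.

    Exactly one surface per identifier is the preferred term; the rest are
    synonyms.
    """

    hpo_id: str
    surface: str
    is_preferred: bool

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("entry surface must be non-empty")
        if not self.hpo_id:
            raise ValidationError("entry hpo_id must be non-empty")


class OntologyDictionary:
    """Surface-term -> HPO-identifier mapping with preferred terms and synonyms."""

    def __init__(self, entries: Iterable[OntologyEntry]):
        self.entries: list[OntologyEntry] = []
        self._by_surface: dict[str, list[OntologyEntry]] = {}
        self._preferred: dict[str, OntologyEntry] = {}
        seen: set[tuple[str, str]] = set()
        for entry in entries:
            key = (entry.surface.casefold(), entry.hpo_id)
            if key in seen:
                raise ValidationError(f"duplicate (surface, hpo_id) pair {key}")
            if entry.is_preferred:
                if entry.hpo_id in self._preferred:
                    raise ValidationError(
                        f"two preferred surfaces for {entry.hpo_id}"
                    )
                self._preferred[entry.hpo_id] = entry
            seen.add(key)
            self.entries.append(entry)
            self._by_surface.setdefault(entry.surface.casefold(), []).append(entry)
        for entry in self.entries:
            if entry.hpo_id not in self._preferred:
                raise ValidationError(f"id {entry.hpo_id} has no preferred surface")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return surface.casefold() in self._by_surface

    def lookup(self, surface: str) -> list[OntologyEntry]:
        """Entries whose surface equals ``surface`` case-insensitively."""
        return list(self._by_surface.get(surface.casefold(), ()))

    @property
    def hpo_ids(self) -> list[str]:
        return list(self._preferred)

    def maps_to(self, surface: str, hpo_id: str) -> bool:
        return any(e.hpo_id == hpo_id for e in self.lookup(surface))


StreamOrPath = Union[str, Path, IO[str], Iterable[str]]


def _iter_lines(source: StreamOrPath) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def load_dictionary(source: StreamOrPath) -> OntologyDictionary:
    """Load a two-column tab-separated dictionary: surface term, HPO identifier.

    The first surface seen for an identifier becomes its preferred term;
    later ones are synonyms. Duplicate rows collapse silently; an id cell
    not matching ``HP:NNNNNNN`` is kept with a warning; an empty term cell
    is a row error; an empty dictionary is unusable and raises.
    """
    rows: list[tuple[str, str]] = []
    for row_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"row {row_no}: expected 2 tab-separated columns")
        term, hpo_id = cells[0].strip(), cells[1].strip()
        if not term:
            raise FormatError(f"row {row_no}: empty term")
        if not HPO_ID_RE.match(hpo_id):
            logger.warning("row %d: identifier %r does not match HP:NNNNNNN", row_no, hpo_id)
        rows.append((term, hpo_id))
    if not rows:
        raise FormatError("empty dictionary stream")
    return dictionary_from_pairs(rows)


def dictionary_from_pairs(pairs: Iterable[tuple[str, str]]) -> OntologyDictionary:
    """Build a dictionary from (surface, hpo_id) pairs; first surface per id is preferred."""
    entries: list[OntologyEntry] = []
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for term, hpo_id in pairs:
        key = (term.casefold(), hpo_id)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        entries.append(OntologyEntry(hpo_id, term, is_preferred=hpo_id not in seen_ids))
        seen_ids.add(hpo_id)
    return OntologyDictionary(entries)


def write_dictionary(target: Union[str, Path, IO[str]], dictionary: OntologyDictionary) -> None:
    """Write the two-column tab-separated dictionary format (preferred terms first per id)."""
    own = isinstance(target, (str, Path))
    fh: IO[str] = open(target, "w", encoding="utf-8", newline="\n") if own else target  # type: ignore[arg-type]
    try:
        for entry in dictionary.entries:
            fh.write(f"{entry.surface}\t{entry.hpo_id}\n")
    finally:
        if own:
            fh.close()


def augment_dictionary(
    dictionary: OntologyDictionary, corpus: Sequence[AnnotatedObservation]
) -> OntologyDictionary:
    """Add training-corpus KEYF surfaces as synonyms; returns a new dictionary.

    For every KEYF mention carrying an HPO id, its surface is added as a
    non-preferred synonym of that id unless the surface already maps to it.
    NORMF mentions are ignored (they are not represented in the ontology);
    KEYF mentions without an id are skipped and counted in a log line. The
    input dictionary is never mutated (superset property).
    """
    extra: list[OntologyEntry] = []
    added: set[tuple[str, str]] = set()
    ids_with_preferred = set(dictionary._preferred)
    n_skipped = 0
    for ann in corpus:
        for m in ann.mentions:
            if m.label != KEYF:
                continue
            if not m.hpo_id:
                n_skipped += 1
                continue
            surface = mention_surface(ann.text, m.fragments)
            key = (surface.casefold(), m.hpo_id)
            if key in added or dictionary.maps_to(surface, m.hpo_id):
                continue
            added.add(key)
            extra.append(
                OntologyEntry(m.hpo_id, surface, is_preferred=m.hpo_id not in ids_with_preferred)
            )
            ids_with_preferred.add(m.hpo_id)
    if n_skipped:
        logger.info("augment_dictionary: %d KEYF mentions without hpo_id skipped", n_skipped)
    return OntologyDictionary(list(dictionary.entries) + extra)


@runtime_checkable
class EncoderContract(Protocol):
    """Text -> fixed-dimension unit-norm vector; deterministic."""

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


@runtime_checkable
class RerankerContract(Protocol):
    """(mention surface, term surface) -> scalar score; deterministic."""

    def score_pair(self, surface: str, term: str) -> float:  # pragma: no cover - protocol
        ...


class HashingNgramEncoder:
    """Hashing character-n-gram embedder (the reference :class:`EncoderContract`).

    Case-folds the text, pads it with ``#`` boundary markers, hashes every
    character n-gram (CRC-32) into a fixed number of buckets, accumulates
    term frequencies and L2-normalizes. Identical strings map to identical
    unit vectors; strings sharing substrings share n-gram mass, so cosine
    similarity tracks lexical overlap.
    """

    def __init__(self, dim: int = 1024, n: int = 3):
        if dim < 1024 or dim & (dim - 1):
            raise ValidationError("dim must be a power of two >= 1024")
        if n < 1:
            raise ValidationError("n-gram size must be >= 1")
        self.dim = dim
        self.n = n

    def embed(self, text: str) -> np.ndarray:
        if not text or not text.strip():
            raise ValidationError("cannot embed empty text (zero information)")
        pad = "#" * (self.n - 1)
        padded = f"{pad}{text.casefold()}{pad}"
        vec = np.zeros(self.dim)
        for i in range(len(padded) - self.n + 1):
            gram = padded[i : i + self.n]
            vec[zlib.crc32(gram.encode("utf-8")) % self.dim] += 1.0
        return vec / np.linalg.norm(vec)


def reference_encoder(dim: int = 1024, n: int = 3) -> HashingNgramEncoder:
    return HashingNgramEncoder(dim=dim, n=n)


class DiceReranker:
    """Token-set Dice coefficient over case-folded word sets (reference reranker)."""

    def score_pair(self, surface: str, term: str) -> float:
        a = set(surface.casefold().split())
        b = set(term.casefold().split())
        if not a and not b:
            return 0.0
        return 2.0 * len(a & b) / (len(a) + len(b))


def reference_reranker() -> DiceReranker:
    return DiceReranker()


@dataclass(frozen=True)
class Candidate:
    """A retrieved dictionary entry with its current score."""

    entry: OntologyEntry
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError("candidate score must be finite")


def _tie_sorted(candidates: list[Candidate]) -> list[Candidate]:
    # Deterministic order: score descending, then surface, then id.
    return sorted(candidates, key=lambda c: (-c.score, c.entry.surface, c.entry.hpo_id))


class EmbeddingIndex:
    """Dense embedding index over dictionary entries, rows aligned to entries."""

    def __init__(self, dictionary: OntologyDictionary, encoder: EncoderContract):
        self.entries = list(dictionary.entries)
        self.encoder = encoder
        if not self.entries:
            raise ValidationError("cannot index an empty dictionary")
        self.matrix = np.vstack([encoder.embed(e.surface) for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


def build_index(dictionary: OntologyDictionary, encoder: EncoderContract) -> EmbeddingIndex:
    """Embed every dictionary surface (one row per entry, synonyms included)."""
    return EmbeddingIndex(dictionary, encoder)


def generate_candidates(surface: str, index: EmbeddingIndex, k: int = 30) -> list[Candidate]:
    """Top-``min(k, |entries|)`` entries by cosine similarity to the surface.

    All vectors are unit-norm so cosine is a dot product; scores are clipped
    into [-1, 1] against floating-point spill. Ties break by surface then id.
    """
    if not surface:
        raise ValidationError("cannot generate candidates for an empty surface")
    if len(index) == 0:
        raise ValidationError("empty index")
    scores = np.clip(index.matrix @ index.encoder.embed(surface), -1.0, 1.0)
    pool = [Candidate(e, float(s)) for e, s in zip(index.entries, scores)]
    return _tie_sorted(pool)[: min(k, len(pool))]


def rerank(
    surface: str, candidates: list[Candidate], reranker: RerankerContract
) -> list[Candidate]:
    """Rescore each candidate with the pair scorer and re-sort (same tie rule).

    The candidate set is unchanged — reranking is a permutation with new
    scores.
    """
    if not candidates:
        raise ValidationError("rerank requires a non-empty candidate list")
    rescored = [Candidate(c.entry, float(reranker.score_pair(surface, c.entry.surface))) for c in candidates]
    return _tie_sorted(rescored)


def normalize_mention(
    surface: str,
    dictionary: OntologyDictionary,
    encoder: EncoderContract,
    reranker: RerankerContract,
    k: int = 30,
    index: EmbeddingIndex | None = None,
) -> str:
    """Full normalization of one mention surface: retrieve, rerank, take top-1."""
    if index is None:
        index = build_index(dictionary, encoder)
    candidates = generate_candidates(surface, index, k)
    return rerank(surface, candidates, reranker)[0].entry.hpo_id


class Normalizer:
    """Reusable normalization component: dictionary + encoder index + reranker.

    Builds the embedding index once; :meth:`normalize` then runs candidate
    generation and reranking per surface.
    """

    def __init__(
        self,
        dictionary: OntologyDictionary,
        encoder: EncoderContract | None = None,
        reranker: RerankerContract | None = None,
        k: int = 30,
    ):
        self.dictionary = dictionary
        self.encoder = encoder if encoder is not None else reference_encoder()
        self.reranker = reranker if reranker is not None else reference_reranker()
        self.k = k
        self.index = build_index(dictionary, self.encoder)

    def candidates(self, surface: str) -> list[Candidate]:
        return generate_candidates(surface, self.index, self.k)

    def normalize(self, surface: str) -> str:
        return rerank(surface, self.candidates(surface), self.reranker)[0].entry.hpo_id
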