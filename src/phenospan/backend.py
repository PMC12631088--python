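"""NER backend contract, low-rank adapter (LoRA) arithmetic, and a stub backend.

The generation contract is deliberately tiny: a backend maps observation
text to one target string parseable by :func:`phenospan.codec.decode_target`.
Fine-tuned seq2seq transformers satisfy it in production; the deterministic
:class:`DictionaryStubBackend` satisfies it at desk scale so the whole
pipeline is testable without models or downloads.

LoRA expresses a weight update to a frozen matrix ``W0 ∈ R^{d×k}`` as the
product of two low-rank factors, ``ΔW = B·A`` with ``B ∈ R^{d×r}``,
``A ∈ R^{r×k}`` and rank ``r ≪ min(d, k)``, merged with the scaling
``W = W0 + (α/r)·B·A`` where α is a constant hyperparameter. Only this
merge arithmetic is in scope here; training the factors is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from ._tokens import strip_punct_span, token_spans
from .codec import SEGMENT_SEPARATOR
from .corpus import KEYF, NORMF
from .exceptions import ValidationError
from .normalize import OntologyDictionary

__all__ = [
    "BackendContract",
    "LowRankUpdate",
    "lora_delta",
    "lora_merge",
    "DictionaryStubBackend",
    "DEFAULT_NEGATION_CUES",
]


@runtime_checkable
class BackendContract(Protocol):
    """A seq2seq NER backend: observation text in, target string out.

    Implementations must be deterministic for a fixed configuration and
    seed, and must emit output parseable by ``decode_target`` (segments the
    decoder cannot parse are skipped there, never fatal).
    """

    def generate(self, text: str) -> str:  # pragma: no cover - protocol
        ...


@dataclass(frozen=True)
class LowRankUpdate:
    """A LoRA update: factors ``A`` (r×k), ``B`` (d×r) and the scaling constant α."""

    A: np.ndarray
    B: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        if A.ndim != 2 or B.ndim != 2:
            raise ValidationError("A and B must be 2-D matrices")
        if B.shape[1] != A.shape[0]:
            raise ValidationError(
                f"rank mismatch: B is {B.shape}, A is {A.shape}; need B.shape[1] == A.shape[0]"
            )
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        d, k = B.shape[0], A.shape[1]
        if self.r > min(d, k):
            raise ValidationError(
                f"rank r={self.r} exceeds min(d, k)=min({d}, {k})"
            )

    @property
    def r(self) -> int:
        return self.A.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Shape (d, k) of the full update this factorization expands to."""
        return (self.B.shape[0], self.A.shape[1])


def lora_delta(update: LowRankUpdate) -> np.ndarray:
    """The unscaled update matrix ``ΔW = B·A`` of shape (d, k)."""
    return update.B @ update.A


def lora_merge(W0: np.ndarray, update: LowRankUpdate) -> np.ndarray:
    """Merge a LoRA update into base weights: ``W0 + (α/r)·B·A``."""
    W0 = np.asarray(W0, dtype=float)
    if W0.shape != update.shape:
        raise ValidationError(
            f"base matrix shape {W0.shape} does not match update shape {update.shape}"
        )
    return W0 + (update.alpha / update.r) * lora_delta(update)


DEFAULT_NEGATION_CUES = ("no", "normal", "intact")


class DictionaryStubBackend:
    """Deterministic dictionary-scanning stand-in for a fine-tuned generator.

    Scans the text left to right for the longest case-insensitive match
    against any dictionary surface, on whitespace-token boundaries with
    token-edge punctuation ignored; matches may not overlap. Each match is
    emitted as a ``KEYF`` segment, flipped to ``NORMF`` when the match is
    immediately preceded by (or begins with) a negation cue such as "no",
    "normal" or "intact".
    """

    def __init__(
        self,
        dictionary: OntologyDictionary,
        negation_cues: Iterable[str] = DEFAULT_NEGATION_CUES,
    ) -> None:
        if not dictionary.entries:
            raise ValidationError("stub backend needs a non-empty dictionary")
        self._cues = frozenset(c.casefold() for c in negation_cues)
        self._surfaces: set[tuple[str, ...]] = set()
        for entry in dictionary.entries:
            toks = tuple(entry.surface.casefold().split())
            if toks:
                self._surfaces.add(toks)
        self._max_len = max(len(t) for t in self._surfaces)

    def generate(self, text: str) -> str:
        spans = token_spans(text)
        cores = []
        for s, e in spans:
            cs, ce = strip_punct_span(text, s, e)
            cores.append((cs, ce, text[cs:ce].casefold()))
        segments = []
        i = 0
        while i < len(cores):
            matched = 0
            for length in range(min(self._max_len, len(cores) - i), 0, -1):
                window = tuple(c[2] for c in cores[i : i + length])
                if window in self._surfaces:
                    matched = length
                    break
            if not matched:
                i += 1
                continue
            start, end = cores[i][0], cores[i + matched - 1][1]
            surface = text[start:end]
            negated = cores[i][2] in self._cues or (i > 0 and cores[i - 1][2] in self._cues)
            label = NORMF if negated else KEYF
            segments.append(f"{label}: {surface}")
            i += matched
        return SEGMENT_SEPARATOR.join(segments)
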