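"""End-to-end orchestration: generate, decode, ground, filter, normalize.

For each observation the pipeline (i) asks the NER backend for a target
string, (ii) decodes it into labeled surfaces, (iii) grounds each surface
to character offsets, (iv) sends key-finding surfaces through the
normalizer for an HPO id while normal findings are kept in the span output
without one, and (v) assembles predicted annotated observations.
Unparseable segments and ungrounded surfaces are counted and reported —
they silently cost recall/precision otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .backend import BackendContract
from .codec import DecodedMention, decode_target
from .corpus import KEYF, AnnotatedObservation, Mention, Observation, mention_surface
from .exceptions import PhenospanError
from .grounding import ground_all
from .normalize import Normalizer

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Predictions plus the loss accounting of the run."""

    predictions: list[AnnotatedObservation] = field(default_factory=list)
    n_skipped_segments: int = 0
    ungrounded: list[tuple[str, DecodedMention]] = field(default_factory=list)


def run_pipeline(
    observations: Sequence[Observation],
    backend: BackendContract,
    normalizer: Normalizer | None,
    max_fragments: int = 3,
) -> PipelineResult:
    """Run extraction (and normalization, when a normalizer is given) end to end.

    Component failures are re-raised with the offending observation id in
    the message. With ``normalizer=None`` the span output carries no ids.
    """
    result = PipelineResult()
    for obs in observations:
        try:
            target = backend.generate(obs.text)
            warnings: list[str] = []
            decoded = decode_target(target, warnings=warnings)
            result.n_skipped_segments += len(warnings)
            mentions, ungrounded = ground_all(obs, decoded, max_fragments)
            for dec in ungrounded:
                result.ungrounded.append((obs.id, dec))
                logger.warning("observation %s: surface %r not groundable", obs.id, dec.surface)
            final: list[Mention] = []
            for m in mentions:
                if normalizer is not None and m.label == KEYF:
                    hpo_id = normalizer.normalize(mention_surface(obs.text, m.fragments))
                    m = Mention(m.label, m.fragments, hpo_id)
                final.append(m)
            result.predictions.append(AnnotatedObservation(obs, final))
        except PhenospanError as exc:
            raise type(exc)(f"observation {obs.id}: {exc}") from exc
    return result
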