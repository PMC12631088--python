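"""Seeded synthetic corpora and toy ontologies.

Emulates the structural regime of dysmorphology physical-examination
annotations: short sectioned observations ("EYES: ...", "HANDS FEET: ...")
containing continuous mentions, non-overlapping discontinuous mentions
(an entity interrupted by modifier tokens), and shared-head overlapping
discontinuous mentions produced by coordination ellipsis ("thumb broad
and elongated" annotated as "thumb broad" + "thumb elongated"), plus a
matching toy ontology dictionary. Everything is reproducible from a seed.

Default rates mirror the corpus this regime models: 14.4% of mentions
discontinuous, 12.8% normal findings, 2-part:3-part discontinuity 358:11,
and an overlap-structure mix of roughly 26% no-overlap, 42% left, 20%
right, 12% multiple.

Design constraints the generator guarantees (and tests rely on):

* every key finding's surface is a dictionary surface, so it carries a
  gold HPO id and exact-surface normalization can recover it;
* within one observation no mention surface (or any of its words) occurs
  twice, so grounding a gold surface has a unique feasible placement;
* each mention's discontinuity and polarity are independent Bernoulli
  draws, so realized corpus rates are exactly binomial in the mention
  count.

Normal findings carry no HPO id here (they are never normalized), and a
continuous normal finding is rendered with a leading negation cue ("no")
inside its span; discontinuous or shared-head normal findings omit the cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    KEYF,
    NORMF,
    AnnotatedObservation,
    Mention,
    Observation,
    SpanFragment,
)
from ._tokens import token_spans
from .exceptions import GenerationError
from .normalize import OntologyDictionary, OntologyEntry, dictionary_from_pairs

__all__ = [
    "PARTS",
    "QUALITIES",
    "MODIFIER_NOUNS",
    "make_dictionary",
    "CorpusConfig",
    "generate_corpus",
    "perturb_predictions",
]

# Vocabulary chosen so that no word is a substring of any other generator
# word (parts, qualities, modifier nouns, fillers, cues, section names):
# this keeps surface placements unambiguous for grounding tests.
PARTS = (
    "thumb", "palate", "helix", "nostril", "clavicle", "sternum", "maxilla",
    "philtrum", "earlobe", "eyebrow", "fontanel", "hallux", "tragus",
    "columella", "glabella", "occiput", "forearm", "kneecap", "ankle",
    "wrist", "elbow", "scapula", "patella", "cornea", "uvula", "gingiva",
)
QUALITIES = (
    "broad", "narrow", "sloping", "prominent", "hypoplastic", "upslanted",
    "downcast", "cupped", "flared", "tapered", "webbed", "ridged",
    "flattened", "rounded", "pointed", "thickened", "elongated",
    "shortened", "asymmetric", "bulbous",
)
MODIFIER_NOUNS = ("crease", "fold", "margin")

# Qualities admitted into 3-word surfaces; keeping this small concentrates
# (quality, noun) families so shared-first-and-last-word pairs exist even
# in modest dictionaries.
_THREE_WORD_QUALITIES = QUALITIES[:6]

_FILLERS = ("mildly", "somewhat", "slightly", "rather", "quite", "faintly")
_CONNECTOR = "and"
_CUE = "no"
_SECTIONS = (
    "EYES", "HANDS FEET", "NECK", "FACE", "MOUTH", "EARS", "NOSE", "CHEST",
    "ABDOMEN", "SKIN",
)

DEFAULT_OVERLAP_MIX = {"no": 0.26, "left": 0.42, "right": 0.20, "multiple": 0.12}
DEFAULT_PARTS_MIX = {2: 358 / 369, 3: 11 / 369}


def make_dictionary(
    n_ids: int,
    synonyms_per_id: int = 0,
    seed: int = 0,
    three_word_fraction: float = 0.25,
) -> OntologyDictionary:
    """Generate a toy ontology dictionary with collision-free surfaces.

    Identifiers are ``HP:`` + zero-padded sequence numbers (synthetic, not
    real HPO concepts). Each id gets one preferred surface plus
    ``synonyms_per_id`` synonyms, drawn without replacement from a
    body-part/quality grammar: two-word surfaces ``"<part> <quality>"``
    ("thumb broad") and three-word surfaces ``"<quality> <part> <noun>"``
    ("broad thumb crease"). All surfaces across the dictionary are distinct.
    """
    if n_ids < 1:
        raise GenerationError("n_ids must be >= 1")
    rng = np.random.default_rng(seed)
    # Pools are grouped (2-word by part, 3-word by quality+noun) so that the
    # consumed surfaces concentrate into shared-head families: any dictionary
    # with a handful of surfaces already contains the pairs the corpus
    # generator needs for overlapping-coordination structures.
    parts = list(PARTS)
    rng.shuffle(parts)
    two_pool = []
    for p in parts:
        qs = list(QUALITIES)
        rng.shuffle(qs)
        two_pool.extend((p, q) for q in qs)
    cells = [(q, m) for q in _THREE_WORD_QUALITIES for m in MODIFIER_NOUNS]
    rng.shuffle(cells)
    three_pool = []
    for q, m in cells:
        ps = list(PARTS)
        rng.shuffle(ps)
        three_pool.extend((q, p, m) for p in ps)
    two_pool.reverse()  # .pop() consumes from the front of the grouped order
    three_pool.reverse()
    needed = n_ids * (1 + synonyms_per_id)
    if needed > len(two_pool) + len(three_pool):
        raise GenerationError(
            f"n_ids/synonyms_per_id require {needed} surfaces; the grammar offers only "
            f"{len(two_pool) + len(three_pool)}"
        )
    pairs: list[tuple[str, str]] = []
    for i in range(n_ids):
        hpo_id = f"HP:{i + 1:07d}"
        for _ in range(1 + synonyms_per_id):
            want_three = rng.random() < three_word_fraction
            if want_three and three_pool:
                combo = three_pool.pop()
            elif two_pool:
                combo = two_pool.pop()
            else:
                combo = three_pool.pop()
            pairs.append((" ".join(combo), hpo_id))
    return dictionary_from_pairs(pairs)


@dataclass
class CorpusConfig:
    """Generator configuration; defaults mirror the modeled corpus regime."""

    n_obs: int = 200
    disjoint_rate: float = 369 / 2562
    normf_rate: float = 329 / 2562
    overlap_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OVERLAP_MIX))
    parts_mix: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PARTS_MIX))
    second_mention_rate: float = 0.5
    filler_rate: float = 0.4
    id_prefix: str = "SYN"

    def validate(self) -> None:
        for key in ("disjoint_rate", "normf_rate", "second_mention_rate", "filler_rate"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"config key {key} must be in [0, 1], got {v}")
        for name, mix, keys in (
            ("overlap_mix", self.overlap_mix, {"no", "left", "right", "multiple"}),
            ("parts_mix", self.parts_mix, {2, 3}),
        ):
            if set(mix) != keys or any(w < 0 for w in mix.values()):
                raise GenerationError(f"config key {name} must weight exactly {sorted(map(str, keys))}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise GenerationError(f"config key {name} must sum to 1")


class _Builder:
    """Accumulates tokens and records each token's character span."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.spans: list[tuple[int, int]] = []
        self.pos = 0

    def add(self, token: str) -> int:
        if self.parts:
            self.pos += 1  # single joining space
        start = self.pos
        self.parts.append(token)
        self.pos += len(token)
        self.spans.append((start, self.pos))
        return len(self.spans) - 1

    def text(self) -> str:
        return " ".join(self.parts)

    def fragments(self, token_groups: list[list[int]]) -> tuple[SpanFragment, ...]:
        frags = []
        for group in token_groups:
            frags.append(SpanFragment(self.spans[group[0]][0], self.spans[group[-1]][1]))
        return tuple(frags)


class _Pools:
    """Usable dictionary entries for one observation, indexed for pair families."""

    def __init__(self, dictionary: OntologyDictionary, rng: np.random.Generator):
        self.rng = rng
        self.two: list[OntologyEntry] = []
        self.three: list[OntologyEntry] = []
        for e in dictionary.entries:
            words = e.surface.split()
            if len(words) == 2:
                self.two.append(e)
            elif len(words) == 3:
                self.three.append(e)
        # Shuffle once per corpus so draws differ across observations.
        self.rng.shuffle(self.two)
        self.rng.shuffle(self.three)
        self.used_words: set[str] = set()

    def reset_observation(self) -> None:
        self.used_words = set()

    def _usable(self, entry: OntologyEntry) -> bool:
        return not any(w in self.used_words for w in entry.surface.split())

    def _consume(self, entry: OntologyEntry) -> OntologyEntry:
        self.used_words.update(entry.surface.split())
        return entry

    def take_any(self, prefer_three: bool = False) -> OntologyEntry | None:
        pools = (self.three, self.two) if prefer_three else (self.two, self.three)
        for pool in pools:
            start = int(self.rng.integers(0, len(pool))) if pool else 0
            for i in range(len(pool)):
                e = pool[(start + i) % len(pool)]
                if self._usable(e):
                    return self._consume(e)
        return None

    def _take_pair(
        self, pool: list[OntologyEntry], key_fn, distinct_fn
    ) -> tuple[OntologyEntry, OntologyEntry] | None:
        groups: dict[object, list[OntologyEntry]] = {}
        for e in pool:
            if self._usable(e):
                groups.setdefault(key_fn(e), []).append(e)
        keys = [k for k, es in groups.items() if len(es) >= 2]
        if not keys:
            return None
        key = keys[int(self.rng.integers(0, len(keys)))]
        es = groups[key]
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                if distinct_fn(es[i], es[j]):
                    a, b = es[i], es[j]
                    self._consume(a)
                    self._consume(b)
                    return a, b
        return None

    def take_shared_first(self):
        """Two 2-word entries sharing the part (first word): left-overlap family."""
        return self._take_pair(
            self.two,
            key_fn=lambda e: e.surface.split()[0],
            distinct_fn=lambda a, b: a.surface.split()[1] != b.surface.split()[1],
        )

    def take_shared_last(self):
        """Two 2-word entries sharing the quality (last word): right-overlap family."""
        return self._take_pair(
            self.two,
            key_fn=lambda e: e.surface.split()[1],
            distinct_fn=lambda a, b: a.surface.split()[0] != b.surface.split()[0],
        )

    def take_shared_ends(self):
        """Two 3-word entries sharing quality and noun: multiple-overlap family."""
        return self._take_pair(
            self.three,
            key_fn=lambda e: (e.surface.split()[0], e.surface.split()[2]),
            distinct_fn=lambda a, b: a.surface.split()[1] != b.surface.split()[1],
        )


@dataclass
class _MentionSpec:
    label: str
    token_groups: list[list[int]]
    hpo_id: str | None


def _choice(rng: np.random.Generator, options: list[str], weights: list[float]) -> str:
    total = sum(weights)
    if total <= 0:
        return options[0]
    return options[int(rng.choice(len(options), p=[w / total for w in weights]))]


def generate_corpus(
    dictionary: OntologyDictionary,
    config: CorpusConfig | None = None,
    seed: int = 0,
) -> list[AnnotatedObservation]:
    """Generate a seeded annotated corpus over the given toy dictionary.

    Each observation holds 1-2 mentions. Per mention, discontinuity and
    polarity are independent Bernoulli draws at the configured rates;
    discontinuous mentions are realized as interrupted spans or shared-head
    coordinations according to ``overlap_mix`` (pair structures require a
    second mention in the observation, so the realized mix is approximate
    while the rates are exact). Raises :class:`GenerationError` naming the
    config key when a requested structure cannot be realized.
    """
    cfg = config or CorpusConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    pools = _Pools(dictionary, rng)
    if not pools.two and not pools.three:
        raise GenerationError("dictionary: no 1-3 word surfaces usable by the generator")
    corpus: list[AnnotatedObservation] = []
    for i in range(cfg.n_obs):
        pools.reset_observation()
        n_units = 1 + int(rng.random() < cfg.second_mention_rate)
        disjoint = [bool(rng.random() < cfg.disjoint_rate) for _ in range(n_units)]
        normf = [bool(rng.random() < cfg.normf_rate) for _ in range(n_units)]
        builder = _Builder()
        section = _SECTIONS[int(rng.integers(0, len(_SECTIONS)))]
        for word in f"{section}:".split():
            builder.add(word)
        specs: list[_MentionSpec] = []
        units = _plan_units(cfg, rng, disjoint, normf)
        for u, unit in enumerate(units):
            if u > 0:
                builder.add(".")
            specs.extend(_realize_unit(unit, builder, pools, cfg, rng))
        builder.add(".")
        text = builder.text()
        mentions = [
            Mention(s.label, builder.fragments(s.token_groups), s.hpo_id) for s in specs
        ]
        mentions.sort(key=lambda m: (m.start, m.end))
        corpus.append(
            AnnotatedObservation(Observation(f"{cfg.id_prefix}{i:05d}", text), mentions)
        )
    return corpus


def _plan_units(cfg, rng, disjoint: list[bool], normf: list[bool]) -> list[dict]:
    """Group the per-mention draws into realization units.

    A unit is either a single mention or a shared-head pair consuming two
    mentions. Disjointness and polarity always follow the Bernoulli draws.
    """
    mix = cfg.overlap_mix
    if len(disjoint) == 2 and disjoint[0] and disjoint[1]:
        denom = mix["multiple"] + mix["no"]
        p_multiple = mix["multiple"] / denom if denom > 0 else 0.5
        if rng.random() < p_multiple:
            return [{"kind": "multiple_pair", "normf": (normf[0], normf[1])}]
        return [
            {"kind": "disjoint", "normf": normf[0]},
            {"kind": "disjoint", "normf": normf[1]},
        ]
    if len(disjoint) == 2 and (disjoint[0] or disjoint[1]):
        d_idx = 0 if disjoint[0] else 1
        c_idx = 1 - d_idx
        cat = _choice(rng, ["no", "left", "right"], [mix["no"], mix["left"], mix["right"]])
        if cat in ("left", "right"):
            return [
                {
                    "kind": f"{cat}_pair",
                    "normf": (normf[d_idx], normf[c_idx]),  # (disjoint member, sibling)
                }
            ]
        return [
            {"kind": "disjoint", "normf": normf[d_idx]},
            {"kind": "continuous", "normf": normf[c_idx]},
        ]
    return [
        {"kind": "disjoint" if d else "continuous", "normf": nf}
        for d, nf in zip(disjoint, normf)
    ]


def _gap(builder: _Builder, pools: _Pools, rng: np.random.Generator) -> None:
    for _ in range(1 + int(rng.random() < 0.5)):
        builder.add(_FILLERS[int(rng.integers(0, len(_FILLERS)))])


def _need(entry, what: str):
    if entry is None:
        raise GenerationError(
            f"dictionary too small to realize {what}; raise n_ids or adjust overlap_mix/parts_mix"
        )
    return entry


def _realize_unit(unit, builder, pools, cfg, rng) -> list[_MentionSpec]:
    kind = unit["kind"]
    if kind == "continuous":
        entry = _need(pools.take_any(), "a continuous mention")
        tokens = []
        if rng.random() < cfg.filler_rate:
            builder.add(_FILLERS[int(rng.integers(0, len(_FILLERS)))])
        label = NORMF if unit["normf"] else KEYF
        if label == NORMF:
            tokens.append(builder.add(_CUE))
        for w in entry.surface.split():
            tokens.append(builder.add(w))
        hpo = entry.hpo_id if label == KEYF else None
        return [_MentionSpec(label, [tokens], hpo)]
    if kind == "disjoint":
        parts = 3 if rng.random() < cfg.parts_mix[3] else 2
        if parts == 3:
            entry = pools.take_any(prefer_three=True)
            if entry is not None and len(entry.surface.split()) != 3:
                parts = 2  # no 3-word surface available; degrade to 2 parts
        else:
            entry = pools.take_any()
        entry = _need(entry, "a discontinuous mention")
        words = entry.surface.split()
        groups = _split_words(words, parts, rng)
        token_groups: list[list[int]] = []
        for gi, group in enumerate(groups):
            if gi > 0:
                _gap(builder, pools, rng)
            token_groups.append([builder.add(w) for w in group])
        label = NORMF if unit["normf"] else KEYF
        hpo = entry.hpo_id if label == KEYF else None
        return [_MentionSpec(label, token_groups, hpo)]
    if kind == "left_pair":
        pair = _need(pools.take_shared_first(), "a left-overlap pair (overlap_mix)")
        sib_entry, disj_entry = pair
        d_normf, s_normf = unit["normf"]
        part = sib_entry.surface.split()[0]
        q_sib = sib_entry.surface.split()[1]
        q_disj = disj_entry.surface.split()[1]
        sib_tokens = []
        if s_normf:
            sib_tokens.append(builder.add(_CUE))
        t_part = builder.add(part)
        sib_tokens.extend([t_part, builder.add(q_sib)])
        builder.add(_CONNECTOR)
        t_q2 = builder.add(q_disj)
        sib_label = NORMF if s_normf else KEYF
        d_label = NORMF if d_normf else KEYF
        return [
            _MentionSpec(sib_label, [sib_tokens], sib_entry.hpo_id if sib_label == KEYF else None),
            _MentionSpec(d_label, [[t_part], [t_q2]], disj_entry.hpo_id if d_label == KEYF else None),
        ]
    if kind == "right_pair":
        pair = _need(pools.take_shared_last(), "a right-overlap pair (overlap_mix)")
        disj_entry, sib_entry = pair
        d_normf, s_normf = unit["normf"]
        p_disj = disj_entry.surface.split()[0]
        p_sib = sib_entry.surface.split()[0]
        quality = sib_entry.surface.split()[1]
        t_p1 = builder.add(p_disj)
        builder.add(_CONNECTOR)
        sib_tokens = []
        if s_normf:
            sib_tokens.append(builder.add(_CUE))
        sib_tokens.append(builder.add(p_sib))
        t_q = builder.add(quality)
        sib_tokens.append(t_q)
        sib_label = NORMF if s_normf else KEYF
        d_label = NORMF if d_normf else KEYF
        return [
            _MentionSpec(d_label, [[t_p1], [t_q]], disj_entry.hpo_id if d_label == KEYF else None),
            _MentionSpec(sib_label, [sib_tokens], sib_entry.hpo_id if sib_label == KEYF else None),
        ]
    if kind == "multiple_pair":
        pair = _need(pools.take_shared_ends(), "a multiple-overlap pair (overlap_mix)")
        e1, e2 = pair
        nf1, nf2 = unit["normf"]
        q = e1.surface.split()[0]
        p1 = e1.surface.split()[1]
        p2 = e2.surface.split()[1]
        noun = e1.surface.split()[2]
        t_q = builder.add(q)
        t_p1 = builder.add(p1)
        builder.add(_CONNECTOR)
        t_p2 = builder.add(p2)
        t_noun = builder.add(noun)
        l1 = NORMF if nf1 else KEYF
        l2 = NORMF if nf2 else KEYF
        return [
            _MentionSpec(l1, [[t_q, t_p1], [t_noun]], e1.hpo_id if l1 == KEYF else None),
            _MentionSpec(l2, [[t_q], [t_p2, t_noun]], e2.hpo_id if l2 == KEYF else None),
        ]
    raise GenerationError(f"unknown unit kind {kind!r}")


def _split_words(words: list[str], parts: int, rng: np.random.Generator) -> list[list[str]]:
    if parts >= len(words):
        return [[w] for w in words]
    if len(words) == 3 and parts == 2:
        return [words[:2], words[2:]] if rng.random() < 0.5 else [words[:1], words[1:]]
    return [words[:1], words[1:]]


def perturb_predictions(
    corpus: list[AnnotatedObservation],
    drop_rate: float = 0.0,
    boundary_shift_rate: float = 0.0,
    id_corrupt_rate: float = 0.0,
    seed: int = 0,
) -> list[AnnotatedObservation]:
    """Derive controlled imperfect predictions from a gold corpus.

    Per mention, independently and in this order: drop it entirely; shift a
    fragment boundary by one whole token (extending or shrinking, whichever
    first yields a structurally valid mention); replace its HPO id with a
    fresh synthetic id. Output is always structurally valid and the input
    corpus is untouched.
    """
    for rate in (drop_rate, boundary_shift_rate, id_corrupt_rate):
        if not 0.0 <= rate <= 1.0:
            raise GenerationError("perturbation rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for ann in corpus:
        spans = token_spans(ann.text)
        kept: list[Mention] = []
        for m in ann.mentions:
            if rng.random() < drop_rate:
                continue
            if rng.random() < boundary_shift_rate:
                m = _shift_boundary(m, spans, len(ann.text))
            if m.hpo_id and rng.random() < id_corrupt_rate:
                new_id = f"HP:{9000000 + int(rng.integers(0, 99999)):07d}"
                if new_id == m.hpo_id:
                    new_id = f"HP:{9999999:07d}"
                m = Mention(m.label, m.fragments, new_id)
            kept.append(m)
        out.append(AnnotatedObservation(ann.observation, kept))
    return out


def _shift_boundary(m: Mention, spans: list[tuple[int, int]], text_len: int) -> Mention:
    """Move one fragment edge by a whole token; fall back to the original mention."""
    first, last = m.fragments[0], m.fragments[-1]
    candidates: list[tuple[SpanFragment, ...]] = []
    # Extend the last fragment over the following token.
    nxt = next((s for s in spans if s[0] > last.end), None)
    if nxt is not None and nxt[1] <= text_len:
        candidates.append(m.fragments[:-1] + (SpanFragment(last.start, nxt[1]),))
    # Shrink the last fragment by its final token (if it covers several).
    inside = [s for s in spans if last.start <= s[0] and s[1] <= last.end]
    if len(inside) >= 2:
        candidates.append(m.fragments[:-1] + (SpanFragment(last.start, inside[-2][1]),))
    # Extend the first fragment over the preceding token.
    prev = next((s for s in reversed(spans) if s[1] < first.start), None)
    if prev is not None:
        candidates.append((SpanFragment(prev[0], first.end),) + m.fragments[1:])
    for frags in candidates:
        try:
            return Mention(m.label, frags, m.hpo_id)
        except Exception:
            continue
    return m
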