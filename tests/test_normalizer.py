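import numpy as np
import pytest

from phenospan import (
    AnnotatedObservation,
    FormatError,
    Mention,
    Observation,
    SpanFragment,
    ValidationError,
    augment_dictionary,
    build_index,
    generate_candidates,
    load_dictionary,
    normalize_mention,
    rerank,
)
from phenospan.corpus import KEYF, NORMF
from phenospan.normalize import (
    Candidate,
    DiceReranker,
    HashingNgramEncoder,
    Normalizer,
    OntologyEntry,
    dictionary_from_pairs,
    reference_encoder,
    reference_reranker,
)

HYPOTONIA_PAIRS = [("Hypotonia", "HP:0001252"), ("Generalized hypotonia", "HP:0001290")]


class TestLoadDictionary:
    def test_two_rows(self):
        d = load_dictionary([f"{t}\t{i}\n" for t, i in HYPOTONIA_PAIRS])
        assert len(d) == 2
        assert all(e.is_preferred for e in d.entries)

    def test_first_surface_per_id_is_preferred(self):
        rows = ["Hypotonia\tHP:0001252\n", "Low muscle tone\tHP:0001252\n"]
        d = load_dictionary(rows)
        flags = {e.surface: e.is_preferred for e in d.entries}
        assert flags == {"Hypotonia": True, "Low muscle tone": False}

    def test_empty_stream_is_error(self):
        with pytest.raises(FormatError):
            load_dictionary([])

    def test_duplicate_rows_collapse(self):
        rows = ["Hypotonia\tHP:0001252\n"] * 3
        assert len(load_dictionary(rows)) == 1

    def test_empty_term_is_row_error(self):
        with pytest.raises(FormatError, match="row 1"):
            load_dictionary(["\tHP:0001252\n"])


class TestAugmentDictionary:
    def _corpus_with(self, label, surface_frags, text, hpo_id):
        obs = Observation("o1", text)
        return [AnnotatedObservation(obs, [Mention(label, surface_frags, hpo_id)])]

    def test_keyf_surface_added_as_synonym(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        text = "HANDS FEET: Both thumbs are long and broad"
        corpus = self._corpus_with(
            KEYF, (SpanFragment(17, 27), SpanFragment(37, 42)), text, "HP:0011304"
        )
        aug = augment_dictionary(d, corpus)
        added = [e for e in aug.entries if e.surface == "thumbs are broad"]
        assert len(added) == 1 and added[0].hpo_id == "HP:0011304"
        assert len(d) == 2  # input untouched

    def test_existing_mapping_not_duplicated(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        corpus = self._corpus_with(KEYF, (SpanFragment(0, 9),), "Hypotonia noted", "HP:0001252")
        assert len(augment_dictionary(d, corpus)) == len(d)

    def test_normf_mentions_ignored(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        corpus = self._corpus_with(NORMF, (SpanFragment(0, 4),), "calm tone today", None)
        assert len(augment_dictionary(d, corpus)) == len(d)

    def test_same_surface_two_ids_keeps_both(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        text = "floppy infant here"
        obs1 = AnnotatedObservation(
            Observation("a", text), [Mention(KEYF, (SpanFragment(0, 6),), "HP:0001252")]
        )
        obs2 = AnnotatedObservation(
            Observation("b", text), [Mention(KEYF, (SpanFragment(0, 6),), "HP:0001290")]
        )
        aug = augment_dictionary(d, [obs1, obs2])
        ids = {e.hpo_id for e in aug.entries if e.surface == "floppy"}
        assert ids == {"HP:0001252", "HP:0001290"}

    def test_superset_property(self, toy_dictionary, synthetic_corpus):
        aug = augment_dictionary(toy_dictionary, synthetic_corpus)
        assert set(toy_dictionary.entries) <= set(aug.entries)


class TestReferenceEncoder:
    def test_unit_norm_and_self_similarity(self):
        enc = reference_encoder()
        v = enc.embed("Hypotonia")
        assert np.isclose(np.linalg.norm(v), 1.0)
        assert np.isclose(v @ enc.embed("Hypotonia"), 1.0)

    def test_shared_substring_scores_higher(self):
        enc = reference_encoder()
        anchor = enc.embed("Hypotonia")
        assert anchor @ enc.embed("Generalized hypotonia") > anchor @ enc.embed("Oral leukoplakia")

    def test_determinism(self):
        a = HashingNgramEncoder().embed("broad thumb")
        b = HashingNgramEncoder().embed("broad thumb")
        assert np.array_equal(a, b)

    def test_dimension_must_be_power_of_two_min_1024(self):
        for bad in (512, 1000, 1025):
            with pytest.raises(ValidationError):
                HashingNgramEncoder(dim=bad)

    def test_empty_text_rejected(self):
        with pytest.raises(ValidationError):
            reference_encoder().embed("   ")


class TestIndexAndCandidates:
    def test_one_row_per_entry(self):
        rows = ["Hypotonia\tHP:0001252\n", "Low tone\tHP:0001252\n", "Floppy\tHP:0001252\n"]
        idx = build_index(load_dictionary(rows), reference_encoder())
        assert len(idx) == 3
        assert {e.hpo_id for e in idx.entries} == {"HP:0001252"}

    def test_rebuild_bitwise_identical(self, flat_dictionary):
        a = build_index(flat_dictionary, reference_encoder())
        b = build_index(flat_dictionary, reference_encoder())
        assert np.array_equal(a.matrix, b.matrix)

    def test_exact_surface_first_with_score_one(self):
        idx = build_index(dictionary_from_pairs(HYPOTONIA_PAIRS), reference_encoder())
        cands = generate_candidates("Hypotonia", idx)
        assert cands[0].entry.surface == "Hypotonia"
        assert cands[0].score == pytest.approx(1.0)

    def test_truncation_to_dictionary_size(self):
        idx = build_index(dictionary_from_pairs(HYPOTONIA_PAIRS), reference_encoder())
        assert len(generate_candidates("tone", idx, k=100)) == 2

    def test_scores_sorted_and_bounded(self, flat_dictionary):
        idx = build_index(flat_dictionary, reference_encoder())
        cands = generate_candidates("broad thumb crease", idx, k=30)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)
        assert all(-1.0 <= s <= 1.0 for s in scores)
        assert len(cands) == 30

    def test_ranking_matches_brute_force_cosine(self):
        """Retrieval equals a brute-force cosine ranking over all entries."""
        pairs = [
            ("broad thumb", "HP:0000010"), ("narrow thumb", "HP:0000011"),
            ("broad hallux", "HP:0000012"), ("thumb crease", "HP:0000013"),
            ("sloping forehead", "HP:0000014"), ("flat philtrum", "HP:0000015"),
            ("cupped helix", "HP:0000016"), ("flared nostril", "HP:0000017"),
            ("pointed chin", "HP:0000018"), ("webbed digit", "HP:0000019"),
        ]
        d = dictionary_from_pairs(pairs)
        enc = reference_encoder()
        idx = build_index(d, enc)
        for surface in ("broad thumb", "thumb broad", "flared helix"):
            q = enc.embed(surface)
            expected = sorted(
                ((float(np.dot(q, enc.embed(e.surface))), e) for e in d.entries),
                key=lambda se: (-min(max(se[0], -1.0), 1.0), se[1].surface, se[1].hpo_id),
            )
            got = generate_candidates(surface, idx, k=5)
            assert [c.entry for c in got] == [e for _, e in expected[:5]]


class TestRerank:
    def _cands(self, d):
        return [Candidate(e, 0.5) for e in d.entries]

    def test_constant_reranker_preserves_tie_order(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)

        class Constant:
            def score_pair(self, s, t):
                return 0.25

        out = rerank("anything", self._cands(d), Constant())
        assert [c.entry.surface for c in out] == ["Generalized hypotonia", "Hypotonia"]

    def test_dice_prefers_full_token_overlap(self):
        d = dictionary_from_pairs(
            [("Hernia", "HP:0100790"), ("Hernia of the abdominal wall", "HP:0004299")]
        )
        out = rerank("Abdominal wall hernia", self._cands(d), DiceReranker())
        assert out[0].entry.surface == "Hernia of the abdominal wall"
        # Dice by hand: 2*3/(3+5) = 0.75 vs 2*1/(3+1) = 0.5
        assert out[0].score == pytest.approx(0.75)
        assert out[1].score == pytest.approx(0.5)

    def test_single_candidate_passthrough(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS[:1])
        out = rerank("Hypotonia", self._cands(d), reference_reranker())
        assert len(out) == 1 and out[0].entry.surface == "Hypotonia"

    def test_rerank_is_a_permutation(self, flat_dictionary):
        idx = build_index(flat_dictionary, reference_encoder())
        cands = generate_candidates("tapered helix margin", idx, k=30)
        out = rerank("tapered helix margin", cands, reference_reranker())
        assert sorted(c.entry.surface for c in out) == sorted(c.entry.surface for c in cands)


class TestNormalizeMention:
    def test_exact_surface_dominates(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        got = normalize_mention("Hypotonia", d, reference_encoder(), reference_reranker())
        assert got == "HP:0001252"

    def test_augmented_synonym_resolves_to_its_id(self):
        d = dictionary_from_pairs(HYPOTONIA_PAIRS)
        text = "HANDS FEET: Both thumbs are long and broad"
        corpus = [
            AnnotatedObservation(
                Observation("o", text),
                [Mention(KEYF, (SpanFragment(17, 27), SpanFragment(37, 42)), "HP:0011304")],
            )
        ]
        aug = augment_dictionary(d, corpus)
        got = normalize_mention("thumbs are broad", aug, reference_encoder(), reference_reranker())
        assert got == "HP:0011304"

    def test_matches_end_to_end_brute_force(self):
        """Top-1 equals a from-scratch scorer over every (surface, term) pair."""
        d = make_small_dictionary()
        enc, rr = reference_encoder(), reference_reranker()
        normalizer = Normalizer(d, enc, rr, k=30)
        for surface in ("broad thumb", "cupped helix fold", "narrow ankle", "thumb margin"):
            # independent scorer: cosine over all entries, keep best 30, Dice-rescale, top-1
            scored = []
            q = enc.embed(surface)
            for e in d.entries:
                scored.append((float(np.dot(q, enc.embed(e.surface))), e))
            scored.sort(key=lambda se: (-se[0], se[1].surface, se[1].hpo_id))
            pool = scored[:30]
            a = set(surface.casefold().split())
            best = None
            for _, e in pool:
                b = set(e.surface.casefold().split())
                dice = 2 * len(a & b) / (len(a) + len(b))
                key = (-dice, e.surface, e.hpo_id)
                if best is None or key < best[0]:
                    best = (key, e)
            assert normalizer.normalize(surface) == best[1].hpo_id

    def test_exact_surface_top1_accuracy_is_total(self, flat_dictionary):
        """Querying any dictionary surface verbatim returns its own id at rank 1."""
        normalizer = Normalizer(flat_dictionary)
        for entry in flat_dictionary.entries:
            cands = normalizer.candidates(entry.surface)
            assert cands[0].entry.hpo_id == entry.hpo_id
            assert cands[0].score == pytest.approx(1.0)
            assert normalizer.normalize(entry.surface) == entry.hpo_id


def make_small_dictionary():
    from phenospan import make_dictionary

    return make_dictionary(n_ids=20, synonyms_per_id=0, seed=9)


class TestOntologyDictionaryInvariants:
    def test_duplicate_pair_rejected(self):
        e = OntologyEntry("HP:0000001", "thumb", True)
        with pytest.raises(ValidationError):
            from phenospan.normalize import OntologyDictionary

            OntologyDictionary([e, OntologyEntry("HP:0000001", "Thumb", False)])

    def test_two_preferred_rejected(self):
        from phenospan.normalize import OntologyDictionary

        with pytest.raises(ValidationError):
            OntologyDictionary(
                [
                    OntologyEntry("HP:0000001", "thumb", True),
                    OntologyEntry("HP:0000001", "pollex", True),
                ]
            )
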