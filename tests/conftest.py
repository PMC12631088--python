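import pytest

from phenospan import (
    AnnotatedObservation,
    CorpusConfig,
    generate_corpus,
    make_dictionary,
    read_annotations,
)

# A miniature gold-standard snippet in the 5-column layout: one observation
# with a continuous NORMF, one with two overlapping KEYFs sharing the head
# "thumbs are" — the second of which is discontinuous.
SNIPPET = (
    "F8D319161DE176F2\tFACE: No facial abnormalities noted within the limitations "
    "of examination.\tHP:0000271\tX\t6-35\n"
    "DC00B8A9EDA2C78\tHANDS FEET: Both thumbs are long and broad\tHP:0011304\tNA\t17-27,37-42\n"
    "DC00B8A9EDA2C78\tHANDS FEET: Both thumbs are long and broad\tHP:0032524\tNA\t17-32\n"
)


@pytest.fixture(scope="session")
def snippet_text() -> str:
    return SNIPPET


@pytest.fixture(scope="session")
def snippet(snippet_text) -> list[AnnotatedObservation]:
    return read_annotations(snippet_text.splitlines(keepends=True))


@pytest.fixture(scope="session")
def toy_dictionary():
    return make_dictionary(n_ids=150, synonyms_per_id=1, seed=3)


@pytest.fixture(scope="session")
def flat_dictionary():
    """No synonyms: every surface maps to its own identifier."""
    return make_dictionary(n_ids=200, synonyms_per_id=0, seed=5)


@pytest.fixture(scope="session")
def synthetic_corpus(toy_dictionary) -> list[AnnotatedObservation]:
    return generate_corpus(toy_dictionary, CorpusConfig(n_obs=300), seed=11)
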