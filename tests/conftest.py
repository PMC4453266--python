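import pytest

from traitspace import (
    DictionaryTagger,
    SpaceConfig,
    build_space,
    make_fixture_bundle,
    represent_corpus,
    score_corpus,
)


@pytest.fixture(scope="session")
def tiny_bundle():
    return make_fixture_bundle("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_space(tiny_bundle):
    return build_space(tiny_bundle.background, SpaceConfig())


@pytest.fixture(scope="session")
def tiny_tagger(tiny_bundle):
    return DictionaryTagger(tiny_bundle.truth.pos_dictionary)


@pytest.fixture(scope="session")
def tiny_scores(tiny_bundle, tiny_space, tiny_tagger):
    reps = represent_corpus(tiny_bundle.labeled, tiny_tagger)
    return score_corpus(
        tiny_space, reps, labels=tiny_bundle.labeled.labels
    )


@pytest.fixture(scope="session")
def small_bundle():
    return make_fixture_bundle("small", seed=7)
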