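import pytest

from reportal import SynthConfig, build_pool, default_schema, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_corpus():
    """300 synthetic sentences; session-scoped because generation is reused widely."""
    return generate_corpus(SynthConfig(n_sentences=300, seed=7))


@pytest.fixture(scope="session")
def small_pool(small_corpus):
    return build_pool(small_corpus)


TINY_TEXT = "Keine rezente Blutung"

TINY_ANN = (
    "T1\tCertainty_descriptor 0 5\tKeine\n"
    "T2\tTime_information 6 13\trezente\n"
    "T3\tMedical_condition 14 21\tBlutung\n"
)


@pytest.fixture()
def tiny_standoff():
    return TINY_TEXT, TINY_ANN
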