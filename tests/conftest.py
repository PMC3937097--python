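import pytest

from semspaces.corpus_io import Corpus, Segment
from semspaces.spaces import IndexVectorConfig
from semspaces.synthetic import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down synthetic bundle shared across module tests."""
    cfg = SynthConfig(
        seed=7,
        vocab_size=400,
        n_topics=8,
        n_synonym_pairs=6,
        n_abbrev_pairs=4,
        segments_per_corpus=4000,
        segment_length=10,
        min_pair_frequency=20,
    )
    return generate_bundle(cfg)


@pytest.fixture
def icfg():
    return IndexVectorConfig(d=200, n_nonzero=8, seed=11)


@pytest.fixture
def tiny_corpus():
    return Corpus(
        name="tiny",
        segments=[
            Segment(id="s0", tokens=("a", "b", "c")),
            Segment(id="s1", tokens=("b", "c", "d", "a")),
            Segment(id="s2", tokens=("c",)),
        ],
    )
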