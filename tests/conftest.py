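import numpy as np
import pytest

from jointcws import (
    JointModelConfig,
    SyntheticSpec,
    build_vocabulary,
    generate_corpus,
    make_batches,
)


@pytest.fixture(scope="session")
def small_corpus():
    """Fifty short records with a clean class signal."""
    spec = SyntheticSpec(n_records=50, seed=3, sentence_length_words=(3, 8))
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocabulary(small_corpus)


@pytest.fixture(scope="session")
def small_batches(small_corpus, small_vocab):
    return make_batches(small_corpus, small_vocab, batch_size=8)


@pytest.fixture()
def tiny_model_config(small_vocab):
    return JointModelConfig(
        vocab_size=len(small_vocab),
        embedding_dim=10,
        recurrent_hidden=7,
        conv_channels_per_width=5,
        dropout=0.0,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
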