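"""Shared fixtures: small generated corpora and trained models.

Expensive artifacts (trained taggers, char LMs) are session-scoped; the
configurations they freeze are the package's reference study conditions in
:mod:`disann.benchmarks`, scaled for a single CPU.
"""

import numpy as np
import pytest

from disann import (
    EmbeddingStack,
    GeneratorConfig,
    TrainingConfig,
    generate_corpus,
    generate_embeddings,
    train_tagger,
)
from disann.benchmarks import charlm_pair
from disann.synthetic import corpus_vocabulary, entity_word_groups


@pytest.fixture(scope="session")
def tiny_task():
    """A small lexicon-separable tagging setup (fast to train on)."""
    train = generate_corpus(GeneratorConfig(seed=101, n_documents=12, acronym_rate=0.0))
    test = generate_corpus(GeneratorConfig(seed=102, n_documents=4,
                                           acronym_rate=0.0, split="test"))
    groups = entity_word_groups(GeneratorConfig().entity_lexicon)
    table = generate_embeddings(corpus_vocabulary(train, test), 16, seed=5, groups=groups)
    return train, test, EmbeddingStack([table])


@pytest.fixture(scope="session")
def tiny_model(tiny_task):
    train, _, stack = tiny_task
    cfg = TrainingConfig(seed=1, epochs=8, hidden_size=16, batch_size=8, lr=0.02)
    return train_tagger(train, stack, cfg)


@pytest.fixture(scope="session")
def char_lms():
    """A trained forward/backward character LM pair on generated raw text."""
    return charlm_pair(seed=3, hidden_dim=16, steps=150)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
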