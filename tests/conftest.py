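import numpy as np
import pytest

import ccsynth as cs
from ccsynth.model import ModelConfig, train


@pytest.fixture(scope="session")
def toy_config():
    """Small simulator configuration shared by read-only tests."""
    return cs.default_config(n_pairs=4000, seed=11)


@pytest.fixture(scope="session")
def toy_pairs(toy_config):
    pairs, truth = cs.generate_pairs(toy_config)
    return pairs, truth


@pytest.fixture(scope="session")
def toy_corpus(toy_config, toy_pairs):
    pairs, _ = toy_pairs
    corpus, vocab, removed = cs.preprocess_text(pairs, toy_config.schema)
    return corpus, vocab, removed


@pytest.fixture(scope="session")
def memorized_model():
    """A tiny model overfit to 10 distinct pairs: greedy decoding of each
    training record must reproduce its training sentence."""
    schema = cs.build_schema([("age", 10, False, True),
                              ("diagnosis", 10, True, True)])
    texts = ["chest pain", "abd pain", "fall at home", "fever and chills",
             "headache now", "elevated bp", "cut finger", "anxiety attack",
             "mvc driver", "preg test"]
    pairs = [cs.RawRecord({"age": [i], "diagnosis": [i]}, t)
             for i, t in enumerate(texts)]
    corpus, vocab, _ = cs.preprocess_text(pairs, schema, min_freq=1)
    config = ModelConfig(record_dim=schema.total_dim, vocab_size=len(vocab),
                         hidden_dim=24, word_embed_dim=12, batch_size=10,
                         max_epochs=500, patience=500, seed=0)
    params, log = train(corpus, corpus, config)
    return params, corpus, log


@pytest.fixture(scope="session")
def trained_small(toy_config, toy_corpus):
    """A modestly trained model on the 4k-pair toy benchmark, for
    conditioning / generation-quality checks."""
    corpus, vocab, _ = toy_corpus
    train_c, val_c, test_c = cs.split_corpus(corpus, seed=3, test_size=1000)
    config = ModelConfig(record_dim=toy_config.schema.total_dim,
                         vocab_size=len(vocab), hidden_dim=40,
                         word_embed_dim=20, max_epochs=60, seed=5)
    params, log = train(train_c, val_c, config)
    return params, (train_c, val_c, test_c), log
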