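import numpy as np
import pytest

import capstriage as ct
from capstriage import model


@pytest.fixture(scope="session")
def reduced_config():
    return model.ModelConfig.reduced()


@pytest.fixture(scope="session")
def separable_corpus():
    """The default synthetic study condition: 400 docs, rates 0.8/0.05."""
    return ct.generate_corpus(ct.SyntheticSpec())


@pytest.fixture(scope="session")
def separable_split(separable_corpus, reduced_config):
    """75/25 train/test split of the separable corpus, indexed for the model."""
    cfg = reduced_config
    tok = ct.tokenize_corpus(separable_corpus, cfg.max_sentences, cfg.max_words)
    rng = np.random.default_rng(1000)
    order = rng.permutation(len(tok))
    n_test = len(tok) // 4
    test = [tok[i] for i in order[:n_test]]
    train = [tok[i] for i in order[n_test:]]
    train_batch, vocab = ct.prepare_corpus(train, cfg)
    test_batch, _ = ct.prepare_corpus(test, cfg, vocab=vocab)
    return train_batch, test_batch, vocab


@pytest.fixture(scope="session")
def trained_state(separable_split, reduced_config):
    """Full model trained once on the separable corpus; shared across tests."""
    train_batch, _, vocab = separable_split
    return model.train_model(train_batch, reduced_config, vocab)


def micro_config(**overrides):
    """Tiny all-dims<=4 configuration used for gradient and parity checks."""
    base = dict(
        embed_dim=3,
        hidden=3,
        batch_size=2,
        epochs=1,
        dropout_embed=0.0,
        dropout_output=0.0,
        conv_windows=(2,),
        conv_feature_maps=4,
        word_heads=1,
        word_dim=2,
        sent_heads=1,
        sent_dim=2,
        capsule_dim=2,
        n_class_capsules=2,
        routing_iters=3,
        max_sentences=2,
        max_words=3,
        seed=7,
    )
    base.update(overrides)
    return model.ModelConfig(**base)


def micro_batch():
    """Two tiny documents over a 4-token vocabulary."""
    from capstriage.corpus_io import IndexedBatch, Vocabulary

    vocab = Vocabulary()
    for i, t in enumerate("abcd"):
        vocab.token_to_index[t] = i + 2
    ids = np.array([[[2, 3, 0], [4, 0, 0]], [[5, 2, 3], [0, 0, 0]]])
    batch = IndexedBatch(ids=ids, labels=np.array([1, 0]), mask=ids > 0)
    return batch, vocab


def jittered_micro_state(seed=3):
    """Micro model with parameters nudged off ReLU/softmax kinks."""
    cfg = micro_config()
    batch, vocab = micro_batch()
    state = model.build_state(cfg, vocab)
    rng = np.random.default_rng(seed)
    for p in state.params.values():
        p.data = p.data + rng.normal(0, 0.05, size=p.data.shape)
    return cfg, batch, vocab, state
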