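import numpy as np
import pytest

from capsicd.embeddings import EmbeddingMatrix, LabelEmbeddingMatrix
from capsicd.network import CapsuleCoder


@pytest.fixture
def tiny_embedding():
    """A 30-token, 6-dimensional embedding table with reserved rows."""
    rng = np.random.default_rng(42)
    vocab = ["<pad>", "<unk>"] + [f"t{i}" for i in range(30)]
    vectors = np.vstack([np.zeros(6), rng.normal(size=(31, 6)) * 0.5])
    return EmbeddingMatrix(vocab=vocab, vectors=vectors)


@pytest.fixture
def tiny_labels():
    rng = np.random.default_rng(43)
    return LabelEmbeddingMatrix(labels=["001", "002", "003"], vectors=rng.normal(size=(3, 6)))


@pytest.fixture
def tiny_model(tiny_embedding, tiny_labels):
    """A deliberately small coder for wiring and gradient tests."""

    def make(**overrides):
        kw = dict(
            embedding=tiny_embedding,
            label_embeddings=tiny_labels,
            hidden_units=4,
            capsule_dim=3,
            routing_iters=3,
            kernel_size=2,
            n_filters=5,
            n_channels=2,
            batch_size=4,
            max_epochs=2,
            seed=7,
        )
        kw.update(overrides)
        return CapsuleCoder(**kw)

    return make


@pytest.fixture
def tiny_notes():
    rng = np.random.default_rng(44)
    X = [[f"t{int(i)}" for i in rng.integers(0, 30, size=n)] for n in (5, 7, 2, 9, 4, 6, 3, 8)]
    y = [{"001"}, {"002", "003"}, {"001", "002"}, {"003"},
         {"001"}, {"002"}, {"001", "003"}, {"002"}]
    return X, y
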