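import numpy as np
import pytest

from smirnet.graphlets import SimilarityNetwork, enumerate_isomers
from smirnet.io import AssociationList, SequenceRecord


@pytest.fixture(scope="session")
def catalogue():
    return enumerate_isomers()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n, p=0.3):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    a = a | a.T
    ids = tuple(f"v{i}" for i in range(n))
    return SimilarityNetwork(ids=ids, adjacency=a, threshold_rule={})


def network_from_edges(ids, edges):
    pos = {v: i for i, v in enumerate(ids)}
    a = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for u, v in edges:
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    return SimilarityNetwork(ids=tuple(ids), adjacency=a, threshold_rule={})


@pytest.fixture
def toy_association():
    """2 SMs x 3 miRNAs with two known pairs."""
    return AssociationList(
        pairs={("s1", "m2"), ("s2", "m3")},
        sm_ids=["s1", "s2"],
        mirna_ids=["m1", "m2", "m3"],
    )


@pytest.fixture
def random_mirna_texts(rng):
    return ["".join(rng.choice(list("ACGT"), 10)) for _ in range(20)]


@pytest.fixture(scope="session")
def overfit_autoencoder():
    """A 64-d autoencoder memorising 20 random 10-char nucleotide strings.

    Session-scoped because training takes a few seconds and several tests
    inspect different facets (capacity, determinism, encoding shape).
    """
    from smirnet.autoencoder import SequenceAutoencoder
    from smirnet.encoding import mirna_vocabulary

    gen = np.random.default_rng(42)
    texts = ["".join(gen.choice(list("ACGT"), 10)) for _ in range(20)]
    model = SequenceAutoencoder(
        latent_dim=64,
        hidden_units=64,
        epochs=400,
        batch_size=20,
        learning_rate=1e-2,
        vocab=mirna_vocabulary(30),
        random_state=0,
    ).fit(texts)
    return texts, model
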