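import numpy as np
import pytest

from sparseddi.hypergraph import DDIHypergraph, DrugFeatureMatrix
from sparseddi.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_graph():
    """5 drugs, 3 side effects, 7 canonical hyperedges."""
    triples = [(0, 1, 0), (0, 2, 0), (1, 2, 1), (0, 3, 1), (2, 3, 2),
               (1, 4, 2), (3, 4, 0)]
    return DDIHypergraph.from_triples(
        [f"d{i}" for i in range(5)], [f"s{i}" for i in range(3)], triples)


@pytest.fixture()
def toy_features(toy_graph, rng):
    values = rng.random((toy_graph.n_drugs, 6))
    return DrugFeatureMatrix(values, [f"f{i}" for i in range(6)])


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-structure dataset shared across training tests."""
    cfg = SyntheticConfig(n_drugs=40, n_side_effects=15, K_D=4, K_S=4,
                          M=1, N1=1, N2=1, r=0.0, delta=0.05, c=4, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def quick_train_config():
    from sparseddi.training import TrainConfig

    return TrainConfig(variant="SPARSEO", latent_dim=5, n_layers=1,
                       epochs=120, learning_rate=0.02, seed=2,
                       hidden_width=12)


@pytest.fixture(scope="session")
def small_trained_model(small_synthetic, quick_train_config):
    from sparseddi.training import fit

    ds = small_synthetic
    return fit(ds.G, ds.F, quick_train_config)
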