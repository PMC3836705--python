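import numpy as np
import pytest

import topknet as tk


@pytest.fixture
def tiny_universe():
    """Directed 2-regulator x 3-gene universe with T = 4 candidate edges."""
    return tk.build_edge_universe(["G1", "G2"], ["G1", "G2", "G3"], directed=True)


@pytest.fixture
def worked_example():
    """The 5-algorithm, 12-edge ensemble whose focal edge carries ranks
    (1, 3.5, 10, 10.5, 12)."""
    return tk.worked_example_ensemble()


@pytest.fixture
def small_gold():
    """A seeded 10-regulator x 30-gene synthetic gold standard (T = 290)."""
    cfg = tk.SyntheticConfig(n_genes=30, n_regulators=10, edge_density=0.1, seed=42)
    return tk.generate_network(cfg)


def random_instance(rng, t_max=12, m_max=6):
    """A random small ensemble + gold standard for oracle cross-checks.

    Rank matrices are built from random scores with deliberate ties (scores
    drawn from a small integer set) so midranks and tie blocks are hit.
    """
    t = int(rng.integers(4, t_max + 1))
    m = int(rng.integers(2, m_max + 1))
    genes = [f"G{i}" for i in range(1, t + 2)]
    universe = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
    assert universe.size == t
    n_true = int(rng.integers(1, t))
    true = frozenset(rng.choice(len(universe.edges), n_true, replace=False).tolist())
    gold = tk.GoldStandard(universe, frozenset(universe.edges[i] for i in true))
    from scipy.stats import rankdata

    scores = rng.integers(0, 5, size=(m, t)).astype(float)
    ranks = np.vstack([rankdata(-row, method="average") for row in scores])
    ensemble = tk.AlgorithmEnsemble(
        tuple(f"a{i}" for i in range(m)), universe, ranks, scores
    )
    return ensemble, gold
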