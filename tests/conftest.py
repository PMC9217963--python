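import numpy as np
import pandas as pd
import pytest

from symnet.data import ItemMatrix, NodeMeta
from symnet.simulate import (SimulationConfig, generate_structured_graph,
                             sample_ising_exact)


@pytest.fixture(scope="session")
def strong_8node_graph():
    """Well-connected 8-node two-community Ising graph with one bridge."""
    names = [f"N{i}" for i in range(8)]
    comm = {n: ("depression" if i < 5 else "psychosis")
            for i, n in enumerate(names)}
    cfg = SimulationConfig(
        p=8, communities=comm, within_weight_range=(0.8, 1.4),
        bridge_edges=[("N1", "N6", 1.0)], within_density=0.6,
        target_marginals={n: 0.3 for n in names}, seed=5,
    )
    return generate_structured_graph(cfg)


@pytest.fixture(scope="session")
def strong_8node_items(strong_8node_graph):
    return sample_ising_exact(strong_8node_graph, 3000, seed=11)


@pytest.fixture()
def toy_binary_items():
    """Tiny deterministic binary table for plumbing tests."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        (rng.random((60, 4)) < 0.4).astype(int),
        columns=["A", "B", "C", "D"],
    )
    return ItemMatrix(vals, [NodeMeta(c) for c in vals.columns])
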