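import numpy as np
import pandas as pd
import pytest

from clusterbn.data import QUAL, QUANT, MixedDataset


@pytest.fixture
def mixed_small():
    """Tiny mixed table: two quantitative, one qualitative variable."""
    df = pd.DataFrame({
        "height": [1.2, 1.5, 1.1, 1.9, 1.4, 1.6],
        "color": pd.Series(["r", "g", "r", "b", "g", "r"], dtype=object),
        "weight": [50.0, 60.0, 45.0, 80.0, 55.0, 65.0],
    })
    return MixedDataset(df, {"height": QUANT, "color": QUAL, "weight": QUANT})


@pytest.fixture
def two_block_dataset():
    """Six quantitative variables in two independent correlated blocks."""
    def make(seed=0, n=500, r=0.9):
        rng = np.random.default_rng(seed)
        cov = (1 - r) * np.eye(3) + r
        b1 = rng.multivariate_normal(np.zeros(3), cov, size=n)
        b2 = rng.multivariate_normal(np.zeros(3), cov, size=n)
        df = pd.DataFrame(np.hstack([b1, b2]),
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        return MixedDataset(df, {c: QUANT for c in df.columns})
    return make


@pytest.fixture
def random_binary_bn():
    """Factory of random fully-parameterized binary networks."""
    from clusterbn.bn import Dag, DiscreteBN

    def make(seed, n=6, p_edge=0.3):
        rng = np.random.default_rng(seed)
        nodes = [f"v{i}" for i in range(n)]
        arcs = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
                if rng.random() < p_edge]
        dag = Dag(nodes, arcs)
        cpts = {}
        for v in nodes:
            q = 2 ** len(dag.parents(v))
            p = rng.uniform(0.05, 0.95, size=(q, 1))
            cpts[v] = np.hstack([p, 1 - p])
        return DiscreteBN(dag, {v: ["0", "1"] for v in nodes}, cpts)
    return make
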