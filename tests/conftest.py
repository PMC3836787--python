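import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from txnet.expression import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with one perfectly correlated pair (A, B)."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0],
            "s2": [2.0, 4.0, 3.0],
            "s3": [3.0, 6.0, 8.0],
            "s4": [4.0, 8.0, 1.0],
        },
        index=["A", "B", "C"],
    )
    groups = {s: "FS" if s in ("s1", "s2") else "NFS" for s in data.columns}
    return ExpressionMatrix(data, groups=groups)


@pytest.fixture
def vip_motif() -> nx.Graph:
    """Node v linked only to hubs H1, H2; each hub carries 5 private leaves.

    k(v) = 2 while h1(v) = 10; h1(H1) = 1 (the single edge v-H2 crossing
    from H1's first ring to its second).
    """
    g = nx.Graph()
    for h in ("H1", "H2"):
        g.add_edge("v", h)
        for l in range(5):
            g.add_edge(h, f"{h}leaf{l}")
    return g


def er_graphs(n_graphs: int, n_max: int, p_range=(0.05, 0.2), seed: int = 0):
    """Seeded Erdős–Rényi test graphs with string node labels."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_graphs):
        n = int(rng.integers(5, n_max + 1))
        p = float(rng.uniform(*p_range))
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        out.append(nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes()}))
    return out
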