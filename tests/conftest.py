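"""Shared fixtures: tiny hand-checkable graphs and random-draw factories."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sigentropy import LINEAR, EdgeList, ExpressionMatrix, SignalingNetwork, build_network


def network_from_graph(g: nx.Graph) -> SignalingNetwork:
    nodes = sorted(str(v) for v in g.nodes)
    h = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
    A = nx.to_scipy_sparse_array(h, nodelist=nodes, format="csr", dtype=float)
    return SignalingNetwork(nodes, sp.csr_matrix(A))


@pytest.fixture
def k3() -> SignalingNetwork:
    """Complete graph on {a, b, c}."""
    return network_from_graph(nx.complete_graph(["a", "b", "c"]))


@pytest.fixture
def path3() -> SignalingNetwork:
    """Path a-b-c."""
    g = nx.Graph([("a", "b"), ("b", "c")])
    return network_from_graph(g)


@pytest.fixture
def star4() -> SignalingNetwork:
    """Star K1,3: hub a with leaves b, c, d."""
    g = nx.Graph([("a", "b"), ("a", "c"), ("a", "d")])
    return network_from_graph(g)


@pytest.fixture
def kite() -> SignalingNetwork:
    """Triangle a-b-c with pendant d attached to c (non-regular, non-star)."""
    g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
    return network_from_graph(g)


def random_connected_graph(rng: np.random.Generator,
                           n_min: int = 4, n_max: int = 30) -> SignalingNetwork:
    """A random connected Erdos-Renyi graph with 4..n_max nodes."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = min(1.0, 2.5 / max(n - 1, 1) + 0.1)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return network_from_graph(g)


def positive_expression(rng: np.random.Generator, n: int) -> np.ndarray:
    """Strictly positive log-normal expression vector."""
    return rng.lognormal(mean=0.0, sigma=1.0, size=n)


@pytest.fixture
def expr_for():
    """Expression-matrix factory aligned to a network's node order."""

    def make(net: SignalingNetwork, columns: dict[str, np.ndarray]
             ) -> ExpressionMatrix:
        df = pd.DataFrame(columns, index=net.nodes)
        return ExpressionMatrix(df, LINEAR)

    return make
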