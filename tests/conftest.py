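import networkx as nx
import numpy as np
import pytest

import priorcd as pc


@pytest.fixture
def small_panel():
    """Default synthetic panel (4 modules of 5 drugs + 20 nulls), seed 11."""
    cfg = pc.SyntheticPanelConfig(rng_seed=11)
    return cfg, pc.generate_panel(cfg)


@pytest.fixture
def path_network():
    """Path a-b-c."""
    return pc.DrugSimilarityNetwork(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def triangle_network():
    return pc.DrugSimilarityNetwork(edges=[("a", "b"), ("b", "c"), ("a", "c")])


def random_network(n_nodes: int, n_edges: int, seed: int) -> pc.DrugSimilarityNetwork:
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    return pc.DrugSimilarityNetwork.from_graph(
        nx.relabel_nodes(g, {i: f"D{i:04d}" for i in g.nodes})
    )


def rwr_direct_solve(net, seeds, cfg=None):
    """Closed-form steady state p = alpha (I - (1-alpha) A)^-1 p0 — the
    independent linear-algebra oracle for the iterative walk."""
    cfg = cfg or pc.RwrConfig()
    nodes, a = pc.column_normalize(net)
    from priorcd.network_propagation import restart_vector

    p0 = restart_vector(nodes, seeds, cfg.p0_mode)
    n = len(nodes)
    m = np.eye(n) - (1.0 - cfg.alpha) * a.toarray()
    return nodes, cfg.alpha * np.linalg.solve(m, p0)
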