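"""Random walk with restart over the drug similarity network.

The walk iterates p(t) = (1 - alpha) * A * p(t-1) + alpha * p0, where A is
the column-normalised adjacency matrix of the (unweighted) network, p0 puts
the restart mass on the seed drugs, and alpha is the restart probability.
The steady-state visiting probabilities are the drug prioritising scores:
drugs closer (in the global network-diffusion sense) to the approved drugs
score higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io_formats import DrugSimilarityNetwork, PriorScoreTable, SeedSet


@dataclass
class RwrConfig:
    """Restart probability, convergence tolerance and restart-vector mode.

    alpha : probability of restarting from the seed set at each step
        (0.7 by default; the walk is insensitive over 0.1–0.9).
    tol : L1 convergence threshold on successive iterates (1e-10).
    p0_mode : 'unit' assigns each seed initial mass 1 (the literal
        construction), 'normalized' assigns 1/|seeds| so p0 sums to one.
        Scores under the two modes differ by the constant factor |seeds|,
        so ranks are identical.
    """

    alpha: float = 0.7
    tol: float = 1e-10
    max_iter: int = 10**6
    p0_mode: str = "unit"
    norm: str = "l1"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.p0_mode not in ("unit", "normalized"):
            raise ValueError(f"unknown p0_mode {self.p0_mode!r}")
        if self.norm not in ("l1", "linf"):
            raise ValueError(f"unknown norm {self.norm!r}")


def column_normalize(
    net: DrugSimilarityNetwork, node_order: list[str] | None = None
) -> tuple[list[str], sparse.csr_matrix]:
    """Column-normalised adjacency: A[i, j] = adj[i, j] / degree(j).

    Columns of isolated nodes are left all-zero (their restart mass leaks,
    matching the literal iteration). Returns (node order, sparse A).
    """
    nodes = node_order or sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    deg = {v: net.graph.degree(v) for v in nodes}
    for u, v in net.graph.edges:
        i, j = index[u], index[v]
        rows.append(i); cols.append(j); vals.append(1.0 / deg[v])
        rows.append(j); cols.append(i); vals.append(1.0 / deg[u])
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return nodes, a


def restart_vector(
    nodes: list[str], seeds: SeedSet, p0_mode: str = "unit"
) -> np.ndarray:
    """Initial probability vector: seed entries 1 (or 1/|seeds|), rest 0."""
    in_net = [v for v in nodes if v in seeds.drug_ids]
    if not in_net:
        raise ValueError("no seed drug is present in the network")
    p0 = np.zeros(len(nodes))
    mass = 1.0 if p0_mode == "unit" else 1.0 / len(in_net)
    for i, v in enumerate(nodes):
        if v in seeds.drug_ids:
            p0[i] = mass
    return p0


def rwr_scores(
    a: sparse.spmatrix, p0: np.ndarray, cfg: RwrConfig
) -> tuple[np.ndarray, int]:
    """Iterate the walk to the steady state; returns (scores, n_iterations)."""
    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.alpha) * (a @ p) + cfg.alpha * p0
        diff = np.abs(p_next - p)
        residual = diff.sum() if cfg.norm == "l1" else diff.max()
        p = p_next
        if residual < cfg.tol:
            return p, it
    raise RuntimeError(
        f"random walk did not converge in {cfg.max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


def rwr(
    net: DrugSimilarityNetwork, seeds: SeedSet, cfg: RwrConfig | None = None
) -> PriorScoreTable:
    """Prioritise every drug in the network by its steady-state visiting
    probability from the seed set; ranks decrease with score, ties broken
    by drug ID."""
    cfg = cfg or RwrConfig()
    nodes, a = column_normalize(net)
    p0 = restart_vector(nodes, seeds, cfg.p0_mode)
    scores, _ = rwr_scores(a, p0, cfg)
    return PriorScoreTable.from_scores(nodes, scores, seed_ids=seeds.drug_ids)
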