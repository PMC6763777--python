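"""Drug–drug functional similarity from pathway-level correlation profiles.

The construction is a correlation of correlations: first each pathway's
activity profile is Pearson-correlated with each drug's activity profile
across the cell-line panel; then two drugs are compared by correlating their
pathway-correlation columns. Edges connect pairs that are either strongly and
significantly correlated (r >= 0.7 at BH FDR <= 0.05) or among each drug's
top 0.05% partners by decreasing correlation; the mRNA- and miRNA-level
networks are merged by edge union.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DrugActivityMatrix, DrugSimilarityNetwork, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pearson correlations with optional two-sided p and BH-FDR matrices."""

    row_ids: list[str]
    col_ids: list[str]
    r: np.ndarray
    p: np.ndarray | None = None
    fdr: np.ndarray | None = None

    def __post_init__(self):
        if self.r.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("correlation matrix shape mismatch")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-12:
            raise ValueError("|r| > 1")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids


def _pairwise_pearson(x: np.ndarray, y: np.ndarray, min_pairs: int = 3) -> float:
    """Pearson r over pairwise-complete observations; NaN when degenerate."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_pairs:
        return math.nan
    xv, yv = x[ok], y[ok]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return math.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def _cross_corr_complete(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rows of a vs rows of b, no missing values (vectorised fast path)."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.clip(az @ bz.T, -1.0, 1.0)


def pathway_drug_correlation(
    pathways: ExpressionMatrix, drugs: DrugActivityMatrix
) -> CorrelationMatrix:
    """Correlate every pathway-activity profile with every drug-activity
    profile across the shared cell lines (pairwise-complete; entries with
    fewer than 3 complete pairs are missing)."""
    shared = [s for s in pathways.sample_ids if s in set(drugs.sample_ids)]
    if not shared:
        raise ValueError("pathway and drug matrices share no samples")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    pa = pathways.data[shared].to_numpy()
    da = drugs.data[shared].to_numpy()
    if not (np.isnan(pa).any() or np.isnan(da).any()):
        r = _cross_corr_complete(pa, da)
    else:
        r = np.empty((pa.shape[0], da.shape[0]))
        for i in range(pa.shape[0]):
            for j in range(da.shape[0]):
                r[i, j] = _pairwise_pearson(pa[i], da[j])
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        logger.warning("%d pathway-drug correlations undefined", n_missing)
    return CorrelationMatrix(list(pathways.feature_ids), list(drugs.drug_ids), r)


def _corr_pvalues(r: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided p of Pearson r via the t transform with the given df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isnan(r) | (df < 1), np.nan, p)


def drug_drug_similarity(pd_corr: CorrelationMatrix) -> CorrelationMatrix:
    """Drug-by-drug Pearson similarity of pathway-correlation columns.

    For each unordered drug pair the correlation is taken over pathways where
    both columns are non-missing (>= 3 required, else the entry is missing);
    two-sided p-values use the t transform with df = #complete pathways - 2
    and are BH-adjusted jointly over all unordered pairs. The diagonal is 1
    and excluded from the FDR pool.
    """
    cols = pd_corr.r.T  # drugs x pathways
    n = cols.shape[0]
    drug_ids = list(pd_corr.col_ids)
    if np.isnan(cols).any():
        r = np.eye(n)
        df = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(cols[i]) & ~np.isnan(cols[j])
                m = int(ok.sum())
                r[i, j] = r[j, i] = (
                    _pairwise_pearson(cols[i], cols[j]) if m >= 3 else math.nan
                )
                df[i, j] = df[j, i] = m - 2
    else:
        if cols.shape[1] < 3:
            raise ValueError("fewer than 3 pathways; similarity undefined")
        r = _cross_corr_complete(cols, cols)
        np.fill_diagonal(r, 1.0)
        df = np.full((n, n), cols.shape[1] - 2, dtype=float)
    n_undef = int(np.isnan(r[np.triu_indices(n, 1)]).sum())
    if n_undef:
        logger.warning("%d drug pairs with < 3 usable pathways", n_undef)

    p = _corr_pvalues(r, df)
    np.fill_diagonal(p, np.nan)  # self-similarity excluded from the FDR pool
    iu = np.triu_indices(n, 1)
    flat_p = p[iu]
    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(flat_p)
    if ok.any():
        q = np.full(flat_p.shape, np.nan)
        q[ok] = multipletests(flat_p[ok], method="fdr_bh")[1]
        fdr[iu] = q
        fdr[(iu[1], iu[0])] = q
    p[(iu[1], iu[0])] = p[iu]
    return CorrelationMatrix(drug_ids, drug_ids, r, p, fdr)


def select_edges(
    dd: CorrelationMatrix,
    r_min: float = 0.7,
    fdr_max: float = 0.05,
    top_frac: float = 0.0005,
    rule: str = "union",
) -> DrugSimilarityNetwork:
    """Apply the edge criteria to a drug-drug similarity matrix.

    A partner e of drug d qualifies when (r >= r_min and FDR <= fdr_max)
    or e ranks in d's top ceil(top_frac * (n-1)) partners by decreasing r
    (ties at the cutoff all included); ``rule='intersect'`` requires both.
    The union over drugs is canonicalised into an undirected network whose
    node set is all drugs (an empty edge set is allowed but logged).
    """
    if not dd.is_square:
        raise ValueError("drug-drug matrix must be square")
    if rule not in ("union", "intersect"):
        raise ValueError(f"unknown edge rule {rule!r}")
    n = len(dd.row_ids)
    r, fdr = dd.r, dd.fdr
    if fdr is None:
        raise ValueError("edge selection requires FDR-adjusted similarities")
    k_top = math.ceil(top_frac * (n - 1)) if top_frac > 0 and n > 1 else 0

    edges: dict[tuple[str, str], float] = {}
    threshold_ok = np.zeros((n, n), dtype=bool)
    top_ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        partners = np.array([j for j in range(n) if j != i and not math.isnan(r[i, j])])
        if partners.size == 0:
            continue
        rv = r[i, partners]
        threshold_ok[i, partners] = (rv >= r_min) & (fdr[i, partners] <= fdr_max)
        if k_top > 0:
            order = partners[np.argsort(-rv, kind="mergesort")]
            if k_top >= order.size:
                cutoff = -np.inf
            else:
                cutoff = r[i, order[k_top - 1]]
            top_ok[i, partners] = rv >= cutoff  # ties at the cutoff included
    qualifies = (
        threshold_ok | top_ok if rule == "union" else threshold_ok & top_ok
    )
    qualifies = qualifies | qualifies.T  # per-drug views union into one edge set
    for i in range(n):
        for j in range(i + 1, n):
            if qualifies[i, j]:
                u, v = sorted((dd.row_ids[i], dd.row_ids[j]))
                edges[(u, v)] = r[i, j]
    net = DrugSimilarityNetwork(nodes=dd.row_ids, edges=edges, weights=edges)
    if net.n_edges == 0:
        logger.warning("edge selection produced an empty network")
    return net


def merge_networks(
    a: DrugSimilarityNetwork, b: DrugSimilarityNetwork
) -> DrugSimilarityNetwork:
    """Union of node sets and edge sets (edge weights kept where present,
    the first network winning on conflicts)."""
    merged = DrugSimilarityNetwork(nodes=a.nodes | b.nodes)
    for src in (b, a):  # add a last so its weights win
        for u, v in src.edges:
            merged.graph.add_edge(u, v)
            w = src.graph[u][v].get("weight")
            if w is not None:
                merged.graph[u][v]["weight"] = w
    return merged
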