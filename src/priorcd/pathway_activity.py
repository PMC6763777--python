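"""Pathway activity inference from expression matrices.

mRNA expression is converted into pathway-activity profiles with single-sample
gene set enrichment (ssGSEA): within one sample, features are ranked by
decreasing expression and the enrichment score is the sum over list positions
of the difference between the weighted in-set ECDF and the uniform out-of-set
ECDF. microRNA pathways are built by hypergeometric overlap of each miRNA's
target genes with each mRNA pathway; optionally, highly overlapping pathways
can be collapsed to a non-redundant collection.

The ssGSEA score here is the raw running-sum statistic with rank weights
r^tau (tau defaults to 0.25); no cross-sample normalisation is applied —
all downstream use is through Pearson correlation, which is invariant to
per-pathway affine rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

MirnaTargetMap = Mapping[str, frozenset[str]]


@dataclass
class SsgseaConfig:
    """Parameters of the single-sample enrichment score.

    weight_exponent : tau >= 0 applied to the rank values of in-set genes
        (tau=0 gives the unweighted Kolmogorov–Smirnov-like running sum).
    """

    weight_exponent: float = 0.25

    def __post_init__(self):
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be nonnegative")


def rank_features(values: pd.Series) -> list[str]:
    """Order features by decreasing value; ties broken by feature ID.

    Implemented as a stable sort on (-value, feature_id) so the ordering is
    identical across platforms. Missing values must be removed beforehand.
    """
    frame = pd.DataFrame({"v": values})
    frame = frame.sort_index(kind="mergesort")
    frame = frame.sort_values("v", ascending=False, kind="mergesort")
    return list(frame.index)


def ssgsea_sample_score(
    ranked_features: Sequence[str],
    gene_set: Iterable[str],
    weight_exponent: float = 0.25,
) -> float:
    """Running-sum enrichment score of one gene set in one ranked sample.

    ``ranked_features`` lists the N features of the sample by decreasing
    expression; the feature at position i (0-based) carries rank value
    r = N - i. With S the in-set positions,

        ES = sum_i [ P_in(i) - P_out(i) ]
        P_in(i)  = sum_{g in S, pos(g) <= i} r_g^tau / sum_{g in S} r_g^tau
        P_out(i) = #{g not in S, pos(g) <= i} / (N - |S|)

    The set must neither be disjoint from nor cover the ranked list.
    """
    n = len(ranked_features)
    in_set = np.fromiter(
        (f in gene_set for f in ranked_features), dtype=bool, count=n
    )
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no member among the ranked features")
    if n_in == n:
        raise ValueError("gene set covers all ranked features")
    ranks = np.arange(n, 0, -1, dtype=float)
    weights = np.where(in_set, ranks**weight_exponent, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def pathway_activity_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: SsgseaConfig | None = None,
) -> ExpressionMatrix:
    """Score every pathway in every sample; returns pathways x samples.

    Pathways with no member measured in ``expr`` are dropped (logged); a
    sample's ranking excludes features missing in that sample. Dropping
    every pathway is an error.
    """
    cfg = cfg or SsgseaConfig()
    measured = set(expr.feature_ids)
    retained = {
        name: members & measured
        for name, members in sets.items()
        if members & measured
    }
    dropped = len(sets) - len(retained)
    if dropped:
        logger.info("dropped %d pathways with no measured member", dropped)
    if not retained:
        raise ValueError("no pathway has any member in the expression matrix")

    scores = np.empty((len(retained), len(expr.sample_ids)))
    names = list(retained)
    for j, sample in enumerate(expr.sample_ids):
        col = expr.data[sample].dropna()
        ranked = rank_features(col)
        for i, name in enumerate(names):
            scores[i, j] = ssgsea_sample_score(
                ranked, retained[name], cfg.weight_exponent
            )
    return ExpressionMatrix(
        pd.DataFrame(scores, index=names, columns=expr.sample_ids)
    )


def hypergeom_overlap_p(k: int, pathway_size: int, target_size: int, universe_size: int) -> float:
    """Exact upper-tail P(X >= k) of drawing ``target_size`` genes from a
    universe of ``universe_size`` containing ``pathway_size`` pathway genes."""
    if not (0 <= k <= min(pathway_size, target_size) <= universe_size):
        raise ValueError(
            f"inconsistent counts k={k}, K={pathway_size}, "
            f"n={target_size}, N={universe_size}"
        )
    return float(stats.hypergeom.sf(k - 1, universe_size, pathway_size, target_size))


def build_mirna_pathways(
    targets: MirnaTargetMap,
    mrna_sets: GeneSetCollection,
    universe: Iterable[str],
    alpha_thresh: float = 0.05,
) -> GeneSetCollection:
    """Assign miRNAs to pathways by hypergeometric target-overlap testing.

    miRNA m joins pathway P when the overlap of its target genes with P
    (both restricted to the universe) has upper-tail p < ``alpha_thresh``.
    Pathways left without any member miRNA are dropped.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    out: dict[str, frozenset[str]] = {}
    for name, members in mrna_sets.items():
        pathway_genes = members & universe
        if not pathway_genes:
            continue
        hits = set()
        for mirna, tgt in targets.items():
            tgt_in = tgt & universe
            if not tgt_in:
                continue
            k = len(tgt_in & pathway_genes)
            p = hypergeom_overlap_p(k, len(pathway_genes), len(tgt_in), len(universe))
            if p < alpha_thresh:
                hits.add(mirna)
        if hits:
            out[name] = frozenset(hits)
    small = sum(1 for s in out.values() if len(s) < 2)
    if small:
        logger.info("%d microRNA pathways have a single member miRNA", small)
    return GeneSetCollection(out)


def _two_way_overlap(a: frozenset, b: frozenset) -> float:
    """min of the two directed overlap fractions (the 'two-way' overlap)."""
    inter = len(a & b)
    return min(inter / len(a), inter / len(b))


def remove_redundant_pathways(
    sets: GeneSetCollection, overlap_thresh: float = 0.80
) -> GeneSetCollection:
    """Greedily collapse pathway pairs whose two-way overlap exceeds the
    threshold, eliminating the smaller set of each offending pair (ties by
    removing the lexicographically later name)."""
    surviving = dict(sets.items())
    while True:
        pairs = [
            (a, b, _two_way_overlap(surviving[a], surviving[b]))
            for a, b in combinations(sorted(surviving), 2)
        ]
        pairs = [p for p in pairs if p[2] > overlap_thresh]
        if not pairs:
            break
        a, b, _ = max(pairs, key=lambda p: p[2])
        if len(surviving[a]) != len(surviving[b]):
            loser = a if len(surviving[a]) < len(surviving[b]) else b
        else:
            loser = max(a, b)
        del surviving[loser]
    removed = len(sets) - len(surviving)
    if removed:
        logger.info("removed %d redundant pathways (two-way overlap > %.0f%%)",
                    removed, 100 * overlap_thresh)
    descriptions = {k: v for k, v in sets.descriptions.items() if k in surviving}
    return GeneSetCollection(surviving, descriptions)
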