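"""Leave-one-out cross-validation and ROC analysis of the prioritisation.

Each approved drug in a seed set is held out in turn, the walk is rerun from
the remaining seeds, and the held-out drug's recovered score and rank among
the candidate drugs are recorded. Pooling held-out scores (positives) against
non-seed scores (negatives) over all rounds yields a ROC curve and its AUROC
— the probability that a random withheld approved drug outranks a random
non-approved drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DrugSimilarityNetwork, SeedSet
from .network_propagation import RwrConfig, column_normalize, restart_vector, rwr_scores


@dataclass
class RocResult:
    """Step ROC curve (thresholds by decreasing score) and its area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class LoocvResult:
    """Per-round held-out scores/ranks plus the pooled negative scores."""

    rounds: pd.DataFrame          # held_out, score, rank, n_candidates
    negative_scores: np.ndarray   # pooled over rounds
    negative_mean_scores: np.ndarray  # per-drug mean over rounds

    @property
    def positive_scores(self) -> np.ndarray:
        return self.rounds["score"].to_numpy()


def loocv_scores(
    net: DrugSimilarityNetwork, seeds: SeedSet, cfg: RwrConfig | None = None
) -> LoocvResult:
    """Hide each seed drug in turn and rescore it from the remaining seeds.

    The held-out drug's rank is taken among itself plus all network drugs
    outside the full seed set (the candidate pool); non-seed scores from
    every round are pooled as the negative class.
    """
    cfg = cfg or RwrConfig()
    seed_ids = sorted(seeds.drug_ids & net.nodes)
    if len(seed_ids) < 2:
        raise ValueError("LOOCV needs at least 2 seed drugs in the network")
    nodes, a = column_normalize(net)
    node_index = {v: i for i, v in enumerate(nodes)}
    non_seed_idx = np.array(
        [i for i, v in enumerate(nodes) if v not in seeds.drug_ids]
    )

    rows = []
    pooled_negatives = []
    neg_sum = np.zeros(len(non_seed_idx))
    for held_out in seed_ids:
        reduced = seeds.without(held_out)
        p0 = restart_vector(nodes, reduced, cfg.p0_mode)
        scores, _ = rwr_scores(a, p0, cfg)
        held_score = scores[node_index[held_out]]
        neg = scores[non_seed_idx]
        # rank among {held-out} + non-seed drugs, ties counted against us
        rank = 1 + int(np.sum(neg > held_score)) + int(np.sum(neg == held_score))
        rows.append(
            {
                "held_out": held_out,
                "score": held_score,
                "rank": rank,
                "n_candidates": len(non_seed_idx) + 1,
            }
        )
        pooled_negatives.append(neg)
        neg_sum += neg
    return LoocvResult(
        rounds=pd.DataFrame(rows),
        negative_scores=np.concatenate(pooled_negatives),
        negative_mean_scores=neg_sum / len(seed_ids),
    )


def roc_auroc(pos_scores, neg_scores) -> RocResult:
    """ROC curve and AUROC from positive and negative score samples.

    AUROC is the Mann–Whitney pair statistic
    (#{p > n} + 0.5 * #{p == n}) / (|P| * |N|), which equals the trapezoidal
    area under the step ROC; ties contribute half weight.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be nonempty")

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = np.array([np.mean(pos >= t) for t in thresholds])
    fpr = np.array([np.mean(neg >= t) for t in thresholds])
    thresholds = np.concatenate([[np.inf], thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])

    greater = np.sum(pos[:, None] > neg[None, :])
    equal = np.sum(pos[:, None] == neg[None, :])
    auroc = float((greater + 0.5 * equal) / (pos.size * neg.size))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auroc=auroc)


def loocv_auroc(
    net: DrugSimilarityNetwork,
    seeds: SeedSet,
    cfg: RwrConfig | None = None,
    negatives: str = "pooled",
) -> tuple[RocResult, LoocvResult]:
    """LOOCV followed by ROC: held-out scores vs non-seed scores.

    ``negatives='pooled'`` pools every round's non-seed scores;
    ``'per-round-mean'`` averages each non-seed drug's score over rounds.
    """
    loocv = loocv_scores(net, seeds, cfg)
    if negatives == "pooled":
        neg = loocv.negative_scores
    elif negatives == "per-round-mean":
        neg = loocv.negative_mean_scores
    else:
        raise ValueError(f"unknown negative-class convention {negatives!r}")
    return roc_auroc(loocv.positive_scores, neg), loocv
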