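from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import priorcd as pc


def ssgsea_oracle(ranked, gene_set, tau):
    """Position-by-position brute-force of the running-sum definition."""
    n = len(ranked)
    in_set = [f in gene_set for f in ranked]
    denom = sum((n - i) ** tau for i, f in enumerate(ranked) if in_set[i])
    n_out = n - sum(in_set)
    es = 0.0
    for i in range(n):
        p_in = sum(
            (n - j) ** tau for j in range(i + 1) if in_set[j]
        ) / denom
        p_out = sum(1 for j in range(i + 1) if not in_set[j]) / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_top_singleton_hand_value(self):
        # N=3, S at the top, tau=1: (1-0)+(1-1/2)+(1-1) = 1.5
        assert pc.ssgsea_sample_score(["g1", "g2", "g3"], {"g1"}, 1.0) == pytest.approx(1.5)

    def test_bottom_singleton_hand_value(self):
        # S at the bottom, tau=0: (0-1/2)+(0-1)+(1-1) = -1.5
        assert pc.ssgsea_sample_score(["g1", "g2", "g3"], {"g3"}, 0.0) == pytest.approx(-1.5)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("tau", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, seed, tau):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        ranked = [f"g{i}" for i in range(n)]
        size = int(rng.integers(1, n))
        gene_set = set(rng.choice(ranked, size=size, replace=False))
        assert pc.ssgsea_sample_score(ranked, gene_set, tau) == pytest.approx(
            ssgsea_oracle(ranked, gene_set, tau)
        )

    def test_set_covering_all_features_is_error(self):
        with pytest.raises(ValueError, match="covers all"):
            pc.ssgsea_sample_score(["g1", "g2"], {"g1", "g2"}, 0.25)

    def test_disjoint_set_is_error(self):
        with pytest.raises(ValueError, match="no member"):
            pc.ssgsea_sample_score(["g1", "g2"], {"zz"}, 0.25)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        gene_set = {"g1", "g5", "g9"}
        r1 = pc.pathway_activity.rank_features(vals)
        r2 = pc.pathway_activity.rank_features(np.exp(vals) * 3 + 1)
        assert r1 == r2
        assert pc.ssgsea_sample_score(r1, gene_set, 0.25) == pc.ssgsea_sample_score(
            r2, gene_set, 0.25
        )


class TestPathwayActivityMatrix:
    def make_expr(self, vals, genes, samples):
        return pc.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))

    def test_unmeasured_pathway_dropped(self):
        expr = self.make_expr(np.eye(3), ["g1", "g2", "g3"], ["s1", "s2", "s3"])
        sets = pc.GeneSetCollection(
            {"P1": frozenset({"g1", "g2"}), "P2": frozenset({"zz"})}
        )
        act = pc.pathway_activity_matrix(expr, sets)
        assert act.feature_ids == ["P1"]

    def test_all_pathways_unmeasured_is_error(self):
        expr = self.make_expr(np.eye(2), ["g1", "g2"], ["s1", "s2"])
        sets = pc.GeneSetCollection({"P1": frozenset({"zz"})})
        with pytest.raises(ValueError, match="no pathway"):
            pc.pathway_activity_matrix(expr, sets)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{i}" for i in range(5)]
        vals = rng.normal(size=(10, 5))
        sets = pc.GeneSetCollection({"P": frozenset(genes[:4])})
        act = pc.pathway_activity_matrix(self.make_expr(vals, genes, samples), sets)
        perm = [3, 1, 4, 0, 2]
        act_p = pc.pathway_activity_matrix(
            self.make_expr(vals[:, perm], genes, [samples[i] for i in perm]), sets
        )
        np.testing.assert_allclose(
            act.data[samples].to_numpy(), act_p.data[samples].to_numpy()
        )

    def test_top_ranked_members_score_higher(self):
        genes = [f"g{i}" for i in range(20)]
        members = frozenset(genes[:5])
        up = np.concatenate([np.full(5, 10.0), np.zeros(15)])
        down = np.concatenate([np.full(5, -10.0), np.zeros(15)])
        expr = self.make_expr(np.column_stack([up, down]), genes, ["hi", "lo"])
        act = pc.pathway_activity_matrix(expr, pc.GeneSetCollection({"P": members}))
        assert act.data.loc["P", "hi"] > act.data.loc["P", "lo"]


def hypergeom_oracle(k, big_k, n, big_n):
    """Exact enumeration over all C(N, n) equally likely draws."""
    universe = list(range(big_n))
    pathway = set(universe[:big_k])
    hits = sum(
        1 for draw in combinations(universe, n) if len(pathway & set(draw)) >= k
    )
    return hits / comb(big_n, n)


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert pc.hypergeom_overlap_p(0, 5, 2, 10) == 1.0

    def test_exact_tail_example(self):
        assert pc.hypergeom_overlap_p(2, 5, 2, 10) == pytest.approx(10 / 45)

    def test_forced_full_overlap_is_one(self):
        assert pc.hypergeom_overlap_p(4, 4, 4, 4) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            pc.hypergeom_overlap_p(3, 2, 2, 10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        big_n = data.draw(st.integers(2, 12))
        big_k = data.draw(st.integers(1, big_n))
        n = data.draw(st.integers(1, big_n))
        k = data.draw(st.integers(0, min(big_k, n)))
        assert pc.hypergeom_overlap_p(k, big_k, n, big_n) == pytest.approx(
            hypergeom_oracle(k, big_k, n, big_n)
        )


class TestMirnaPathways:
    def test_disjoint_targets_join_nothing(self):
        sets = pc.GeneSetCollection({"P": frozenset({"g1", "g2"})})
        out = pc.build_mirna_pathways(
            {"m": frozenset({"g8", "g9"})}, sets, {f"g{i}" for i in range(10)}
        )
        assert len(out) == 0

    def test_perfect_overlap_is_member(self):
        universe = {f"g{i}" for i in range(10)}
        pathway = frozenset(list(sorted(universe))[:5])
        sets = pc.GeneSetCollection({"P": pathway})
        out = pc.build_mirna_pathways({"m": pathway}, sets, universe)
        # p = 1/C(10,5) ~ 0.00397 < 0.05
        assert out["P"] == {"m"}

    def test_zero_threshold_empties_collection(self):
        universe = {f"g{i}" for i in range(10)}
        pathway = frozenset(list(sorted(universe))[:5])
        sets = pc.GeneSetCollection({"P": pathway})
        out = pc.build_mirna_pathways({"m": pathway}, sets, universe, alpha_thresh=0.0)
        assert len(out) == 0

    def test_empty_universe_is_error(self):
        sets = pc.GeneSetCollection({"P": frozenset({"g1"})})
        with pytest.raises(ValueError, match="universe"):
            pc.build_mirna_pathways({"m": frozenset({"g1"})}, sets, set())


class TestRemoveRedundant:
    def test_smaller_of_overlapping_pair_removed(self):
        a = frozenset(f"g{i}" for i in range(5))
        b = a | {"g99"}
        out = pc.remove_redundant_pathways(
            pc.GeneSetCollection({"A": a, "B": b})
        )
        assert set(out) == {"B"}

    def test_disjoint_unchanged(self):
        sets = pc.GeneSetCollection(
            {"A": frozenset({"g1"}), "B": frozenset({"g2"})}
        )
        assert set(pc.remove_redundant_pathways(sets)) == {"A", "B"}

    def test_identical_duplicate_keeps_exactly_one(self):
        s = frozenset({"g1", "g2"})
        out = pc.remove_redundant_pathways(pc.GeneSetCollection({"X": s, "Y": s}))
        assert set(out) == {"X"}  # lexicographically later name removed

    @pytest.mark.parametrize("seed", range(4))
    def test_output_is_overlap_free(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"P{j}": frozenset(
                rng.choice(genes, size=int(rng.integers(3, 12)), replace=False)
            )
            for j in range(12)
        }
        out = pc.remove_redundant_pathways(pc.GeneSetCollection(sets))
        for a, b in combinations(out, 2):
            inter = len(out[a] & out[b])
            assert min(inter / len(out[a]), inter / len(out[b])) <= 0.80
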