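import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import priorcd as pc

from conftest import random_network


def expr(vals, ids, samples):
    return pc.ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=samples))


def acts(vals, ids, samples):
    return pc.DrugActivityMatrix(pd.DataFrame(vals, index=ids, columns=samples))


SAMPLES = ["s1", "s2", "s3", "s4"]


class TestPathwayDrugCorrelation:
    def test_affine_transform_gives_r_one(self):
        p = expr([[1.0, 2, 3, 4]], ["P"], SAMPLES)
        d = acts([[3.0, 5, 7, 9]], ["d"], SAMPLES)
        assert pc.pathway_drug_correlation(p, d).r[0, 0] == pytest.approx(1.0)

    def test_negation_gives_r_minus_one(self):
        p = expr([[1.0, 2, 3, 4]], ["P"], SAMPLES)
        d = acts([[-1.0, -2, -3, -4]], ["d"], SAMPLES)
        assert pc.pathway_drug_correlation(p, d).r[0, 0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        p = expr([[1.0, 2, 3, 4]], ["P"], SAMPLES)
        d = acts([[2.0, 1, 4, 3]], ["d"], SAMPLES)
        assert pc.pathway_drug_correlation(p, d).r[0, 0] == pytest.approx(0.6)

    def test_pairwise_complete_and_min_pairs(self):
        p = expr([[1.0, 2, 3, 4]], ["P"], SAMPLES)
        d = acts([[2.0, 1, 4, np.nan], [1.0, np.nan, np.nan, 2.0]], ["d1", "d2"],
                 SAMPLES)
        r = pc.pathway_drug_correlation(p, d).r
        assert r[0, 0] == pytest.approx(stats.pearsonr([1, 2, 3], [2, 1, 4])[0])
        assert math.isnan(r[0, 1])  # only 2 complete pairs

    def test_no_shared_samples_is_error(self):
        p = expr([[1.0, 2, 3]], ["P"], ["a", "b", "c"])
        d = acts([[1.0, 2, 3]], ["d"], ["x", "y", "z"])
        with pytest.raises(ValueError, match="share no samples"):
            pc.pathway_drug_correlation(p, d)


class TestDrugDrugSimilarity:
    def make_pd(self, r):
        r = np.asarray(r, dtype=float)
        return pc.CorrelationMatrix(
            [f"P{i}" for i in range(r.shape[0])],
            [f"d{j}" for j in range(r.shape[1])],
            r,
        )

    def test_identical_columns_give_r_one(self):
        col = np.array([0.1, -0.5, 0.8, 0.3])
        dd = pc.drug_drug_similarity(self.make_pd(np.column_stack([col, col])))
        assert dd.r[0, 1] == pytest.approx(1.0)

    def test_diagonal_one_and_excluded_from_fdr(self):
        rng = np.random.default_rng(0)
        dd = pc.drug_drug_similarity(self.make_pd(rng.uniform(-1, 1, size=(6, 4))))
        np.testing.assert_allclose(np.diag(dd.r), 1.0)
        assert np.isnan(np.diag(dd.p)).all() and np.isnan(np.diag(dd.fdr)).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_pair_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.uniform(-1, 1, size=(8, 7))  # 8 pathways x 7 drugs
        dd = pc.drug_drug_similarity(self.make_pd(mat))
        pairs = []
        for i in range(7):
            for j in range(i + 1, 7):
                r, p = stats.pearsonr(mat[:, i], mat[:, j])
                assert dd.r[i, j] == pytest.approx(r)
                assert dd.p[i, j] == pytest.approx(p)
                pairs.append(p)
        from statsmodels.stats.multitest import multipletests

        expected_q = multipletests(pairs, method="fdr_bh")[1]
        got = [dd.fdr[i, j] for i in range(7) for j in range(i + 1, 7)]
        np.testing.assert_allclose(got, expected_q)

    def test_pairs_with_few_usable_pathways_are_missing(self):
        mat = np.full((4, 3), np.nan)
        mat[:, 0] = [0.1, 0.2, 0.3, 0.4]
        mat[:2, 1] = [0.5, 0.1]  # only 2 usable pathways vs d0
        mat[:, 2] = [0.4, 0.1, 0.2, 0.9]
        dd = pc.drug_drug_similarity(self.make_pd(mat))
        assert math.isnan(dd.r[0, 1])
        assert not math.isnan(dd.r[0, 2])


class TestSelectEdges:
    def square(self, r, fdr):
        n = r.shape[0]
        ids = [f"d{i}" for i in range(n)]
        return pc.CorrelationMatrix(ids, ids, r, fdr=fdr)

    def test_strong_significant_matrix_gives_complete_graph(self):
        r = np.full((3, 3), 0.9)
        np.fill_diagonal(r, 1.0)
        net = pc.select_edges(self.square(r, np.full((3, 3), 0.01)))
        assert net.n_edges == 3

    def test_top_rank_rule_guarantees_min_degree(self):
        # 2001 drugs, one with all r below threshold still gets ceil(0.0005*2000)=1 edge
        n = 2001
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.3, 0.3, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = pc.select_edges(self.square(r, np.ones((n, n))))
        degs = net.degree_sequence()
        assert min(degs.values()) >= 1
        assert math.ceil(0.0005 * (n - 1)) == 1

    def test_threshold_limits_give_empty_network(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, size=(5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = pc.select_edges(self.square(r, np.ones((5, 5))), r_min=1.01, top_frac=0.0)
        assert net.n_edges == 0 and net.n_nodes == 5

    def test_order_independence(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(-1, 1, size=(10, 8))
        dd = pc.drug_drug_similarity(
            pc.CorrelationMatrix(
                [f"P{i}" for i in range(10)], [f"d{j}" for j in range(8)], base
            )
        )
        net = pc.select_edges(dd, top_frac=0.2)
        perm = np.random.default_rng(3).permutation(8)
        dd_p = pc.drug_drug_similarity(
            pc.CorrelationMatrix(
                [f"P{i}" for i in range(10)],
                [f"d{j}" for j in perm],
                base[:, perm],
            )
        )
        net_p = pc.select_edges(dd_p, top_frac=0.2)
        assert net.edges == net_p.edges


class TestMergeNetworks:
    def test_empty_is_identity_element(self):
        n = pc.DrugSimilarityNetwork(edges=[("a", "b")])
        merged = pc.merge_networks(n, pc.DrugSimilarityNetwork())
        assert merged == n

    def test_union_of_edges(self):
        a = pc.DrugSimilarityNetwork(edges=[("a", "b")])
        b = pc.DrugSimilarityNetwork(edges=[("b", "c")])
        assert pc.merge_networks(a, b).edges == {("a", "b"), ("b", "c")}

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_subadditive(self, seed):
        a = random_network(12, 15, seed)
        b = random_network(12, 15, seed + 100)
        merged = pc.merge_networks(a, b)
        assert merged.n_edges <= a.n_edges + b.n_edges
        if not (a.edges & b.edges):
            assert merged.n_edges == a.n_edges + b.n_edges
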