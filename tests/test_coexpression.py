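"""PCC matrix, threshold calibration, mutual rank and network assembly,
checked against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from ricenet import (
    CorrelationMatrix, ExpressionCompendium, analytic_null_pcc_quantile,
    build_network, calibrate_pcc_threshold, mutual_rank,
    network_from_compendium, pearson_matrix,
)
from ricenet.coexpression import CoexpressionError

from conftest import make_compendium


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass textbook formula: sum((x-xb)(y-yb)) / sqrt(ssx * ssy)."""
    xb, yb = sum(x) / len(x), sum(y) / len(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    ssx = sum((xi - xb) ** 2 for xi in x)
    ssy = sum((yi - yb) ** 2 for yi in y)
    return num / math.sqrt(ssx * ssy)


def mr_oracle(pcc: np.ndarray) -> np.ndarray:
    """Exhaustive sort-and-lookup mutual rank with stable gene-order ties."""
    n = pcc.shape[0]
    rank = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        partners.sort(key=lambda j: (-pcc[i, j], j))
        for pos, j in enumerate(partners, start=1):
            rank[i, j] = pos
    mr = np.sqrt(rank * rank.T)
    np.fill_diagonal(mr, 0.0)
    return mr


class TestPearson:
    def test_matches_formula_oracle(self):
        comp = make_compendium(3, 4, seed=7)
        corr = pearson_matrix(comp)
        x = comp.values.to_numpy()
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else pearson_oracle(x[i], x[j])
                assert corr.pcc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_self_correlation_is_one_and_anticorrelation_minus_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        values = pd.DataFrame([base, 10.0 - base], index=["g1", "g2"],
                              columns=[f"s{i}" for i in range(5)])
        corr = pearson_matrix(ExpressionCompendium(values))
        assert corr.pcc[0, 0] == 1.0
        assert corr.pcc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_under_positive_affine_rescaling(self, rng):
        comp = make_compendium(20, 15, seed=3)
        corr = pearson_matrix(comp)
        alpha = rng.uniform(0.1, 10, size=20)
        beta = rng.uniform(-5, 5, size=20)
        scaled = ExpressionCompendium(
            comp.values.mul(alpha, axis=0).add(beta, axis=0),
            comp.samples_meta,
        )
        corr2 = pearson_matrix(scaled)
        np.testing.assert_allclose(corr2.pcc, corr.pcc, atol=1e-9)

    @pytest.mark.parametrize("block_size", [1, 7, 64])
    def test_blockwise_equals_whole_matrix(self, block_size):
        comp = make_compendium(100, 20, seed=9)
        whole = pearson_matrix(comp).pcc
        blocked = pearson_matrix(comp, block_size=block_size).pcc
        np.testing.assert_allclose(blocked, whole, rtol=0, atol=1e-12)

    def test_blockwise_and_whole_yield_identical_edge_sets(self):
        comp = make_compendium(500, 30, seed=21)
        edges = {}
        for label, bs in [("whole", None), ("blocked", 64)]:
            corr = pearson_matrix(comp, block_size=bs)
            mr = mutual_rank(corr, block_size=bs)
            net = build_network(corr, mr, pcc_min=0.3, mr_max=10)
            edges[label] = {frozenset(e) for e in net.graph.edges}
        assert edges["whole"] == edges["blocked"]

    def test_constant_row_is_hard_error(self):
        values = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                              index=["flat", "ok"], columns=list("abc"))
        with pytest.raises(CoexpressionError, match="constant"):
            pearson_matrix(ExpressionCompendium(values))

    def test_too_few_samples_rejected(self):
        comp = make_compendium(5, 2, seed=0)
        with pytest.raises(CoexpressionError, match="samples"):
            pearson_matrix(comp)


class TestCalibration:
    def test_percentile_100_is_maximum_sampled_pair(self):
        comp = make_compendium(40, 10, seed=1)
        cal = calibrate_pcc_threshold(comp, n_random=40, percentile=100, seed=0)
        corr = pearson_matrix(comp)
        iu = np.triu_indices(40, k=1)
        assert cal.threshold == pytest.approx(corr.pcc[iu].max(), abs=1e-12)
        assert cal.n_pairs == 40 * 39 // 2

    def test_deterministic_given_seed(self):
        comp = make_compendium(60, 12, seed=2)
        c1 = calibrate_pcc_threshold(comp, n_random=30, seed=5)
        c2 = calibrate_pcc_threshold(comp, n_random=30, seed=5)
        assert c1.threshold == c2.threshold

    def test_matches_analytic_null_quantile_for_iid_profiles(self):
        """99th percentile of sampled pairwise PCCs on iid-normal profiles
        agrees with the closed-form t-based null quantile."""
        comp = make_compendium(700, 176, seed=10)
        cal = calibrate_pcc_threshold(comp, n_random=600, percentile=99, seed=4)
        r_star = analytic_null_pcc_quantile(176, 99)
        assert cal.threshold == pytest.approx(r_star, abs=0.012)

    def test_degenerate_requests_rejected(self):
        comp = make_compendium(10, 5, seed=0)
        with pytest.raises(CoexpressionError):
            calibrate_pcc_threshold(comp, n_random=1)
        with pytest.raises(CoexpressionError):
            calibrate_pcc_threshold(comp, n_random=11)
        with pytest.raises(CoexpressionError):
            calibrate_pcc_threshold(comp, n_random=5, percentile=0.0)


class TestMutualRank:
    def test_two_genes_are_mutual_top_partners(self):
        comp = make_compendium(2, 6, seed=3)
        mr = mutual_rank(pearson_matrix(comp))
        assert mr[0, 1] == 1.0
        assert mr[1, 0] == 1.0

    def test_matches_brute_force_oracle_on_hand_matrix(self):
        pcc = np.array([
            [1.00, 0.90, 0.10, -0.3, 0.50],
            [0.90, 1.00, 0.40, 0.20, 0.10],
            [0.10, 0.40, 1.00, 0.70, 0.60],
            [-0.3, 0.20, 0.70, 1.00, 0.80],
            [0.50, 0.10, 0.60, 0.80, 1.00],
        ])
        corr = CorrelationMatrix([f"g{i}" for i in range(5)], pcc)
        np.testing.assert_allclose(mutual_rank(corr), mr_oracle(pcc),
                                   atol=1e-12)

    def test_symmetric_and_in_range(self):
        comp = make_compendium(25, 10, seed=8)
        mr = mutual_rank(pearson_matrix(comp))
        np.testing.assert_array_equal(mr, mr.T)
        off = mr[~np.eye(25, dtype=bool)]
        assert off.min() >= 1.0
        assert off.max() <= 24.0

    def test_mr_equals_one_iff_reciprocal_best_partners(self):
        comp = make_compendium(30, 8, seed=12)
        corr = pearson_matrix(comp)
        mr = mutual_rank(corr)
        pcc = corr.pcc.copy()
        np.fill_diagonal(pcc, -np.inf)
        best = np.argmax(pcc, axis=1)
        for i in range(30):
            for j in range(i + 1, 30):
                mutual_best = best[i] == j and best[j] == i
                assert (mr[i, j] == 1.0) == mutual_best

    def test_tied_correlations_break_by_gene_order(self):
        pcc = np.array([
            [1.0, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.2, 0.1],
            [0.5, 0.2, 1.0, 0.1],
            [0.5, 0.1, 0.1, 1.0],
        ])
        corr = CorrelationMatrix(list("abcd"), pcc)
        np.testing.assert_allclose(mutual_rank(corr), mr_oracle(pcc))

    @pytest.mark.parametrize("block_size", [3, 16])
    def test_blockwise_ranks_equal_whole(self, block_size):
        comp = make_compendium(50, 9, seed=4)
        corr = pearson_matrix(comp)
        np.testing.assert_array_equal(
            mutual_rank(corr, block_size=block_size), mutual_rank(corr)
        )


class TestBuildNetwork:
    def test_all_pcc_below_threshold_gives_empty_network(self):
        comp = make_compendium(10, 8, seed=6)
        corr = pearson_matrix(comp)
        mr = mutual_rank(corr)
        net = build_network(corr, mr, pcc_min=1.0, mr_max=10)
        assert net.node_count == 0
        assert net.edge_count == 0

    def test_edges_match_pairwise_filter_oracle(self):
        comp = make_compendium(6, 10, seed=11)
        corr = pearson_matrix(comp)
        mr = mutual_rank(corr)
        pcc_min, mr_max = 0.1, 3.0
        net = build_network(corr, mr, pcc_min, mr_max)
        expected = set()
        for i in range(6):
            for j in range(i + 1, 6):
                if corr.pcc[i, j] > pcc_min and mr[i, j] < mr_max:
                    expected.add(frozenset((corr.gene_ids[i], corr.gene_ids[j])))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected
        for node in net.graph.nodes:
            assert net.graph.degree(node) >= 1

    def test_thresholds_are_strict_inequalities(self):
        pcc = np.array([[1.0, 0.64], [0.64, 1.0]])
        corr = CorrelationMatrix(["a", "b"], pcc)
        mr = mutual_rank(corr)  # MR = 1 for the only pair
        assert build_network(corr, mr, 0.64, 10).edge_count == 0  # pcc == min
        assert build_network(corr, mr, 0.63, 1.0).edge_count == 0  # mr == max
        assert build_network(corr, mr, 0.63, 1.5).edge_count == 1

    def test_monotone_in_both_thresholds(self):
        comp = make_compendium(40, 12, seed=13)
        corr = pearson_matrix(comp)
        mr = mutual_rank(corr)
        base = {frozenset(e)
                for e in build_network(corr, mr, 0.2, 8).graph.edges}
        tighter_pcc = {frozenset(e)
                       for e in build_network(corr, mr, 0.4, 8).graph.edges}
        tighter_mr = {frozenset(e)
                      for e in build_network(corr, mr, 0.2, 4).graph.edges}
        assert tighter_pcc <= base
        assert tighter_mr <= base

    def test_edge_table_sorted_and_symmetric_free(self):
        comp = make_compendium(15, 10, seed=5)
        net = network_from_compendium(comp, pcc_min=0.2, mr_max=6)
        tab = net.edge_table()
        assert (tab["gene_a"] < tab["gene_b"]).all()
        assert tab.equals(tab.sort_values(["gene_a", "gene_b"]).reset_index(drop=True))

    def test_export_formats(self, tmp_path):
        comp = make_compendium(15, 10, seed=5)
        net = network_from_compendium(comp, pcc_min=0.2, mr_max=6)
        net.write_edges_tsv(tmp_path / "e.tsv")
        net.write_sif(tmp_path / "e.sif")
        net.write_graphml(tmp_path / "e.graphml")
        sif_lines = (tmp_path / "e.sif").read_text().splitlines()
        assert len(sif_lines) == net.edge_count
        assert all(l.split("\t")[1] == "co" for l in sif_lines)
        import networkx as nx
        g = nx.read_graphml(tmp_path / "e.graphml")
        assert g.number_of_edges() == net.edge_count
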