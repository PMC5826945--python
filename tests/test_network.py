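import itertools

import networkx as nx
import numpy as np
import pytest

from sczprio.errors import ParameterError, ValidationError
from sczprio.network import (
    coexpression_network,
    coexpression_permutation_test,
    cross_connectivity,
    per_gene_cross_edges,
    ppi_permutation_test,
)
from conftest import make_expression


def brute_force_cross(candidates, reference, net):
    """O(|A|*|B|) oracle: count edges between candidates\\reference and reference."""
    cand = set(candidates) - set(reference)
    count = 0
    for c in cand:
        for r in set(reference):
            if net.has_edge(c, r):
                count += 1
    return count


class TestCrossConnectivity:
    def test_disjoint_no_edges(self):
        net = nx.Graph([("x", "y")])
        assert cross_connectivity({"a"}, {"b"}, net) == 0

    def test_internal_edges_excluded(self):
        net = nx.Graph([("a", "c"), ("a", "d"), ("c", "d"), ("a", "b")])
        assert cross_connectivity({"a", "b"}, {"c", "d"}, net) == 2

    def test_symmetry(self, rng):
        genes = [f"g{i}" for i in range(12)]
        net = nx.gnp_random_graph(12, 0.3, seed=4)
        net = nx.relabel_nodes(net, dict(enumerate(genes)))
        a = set(rng.choice(genes, 4, replace=False))
        b = set(rng.choice(genes, 4, replace=False))
        assert cross_connectivity(a, b, net) == cross_connectivity(b, a, net)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 20))
            genes = [f"g{i}" for i in range(n)]
            net = nx.gnp_random_graph(n, float(rng.uniform(0, 0.6)),
                                      seed=int(rng.integers(1 << 30)))
            net = nx.relabel_nodes(net, dict(enumerate(genes)))
            a = set(rng.choice(genes, int(rng.integers(1, n)), replace=False))
            b = set(rng.choice(genes, int(rng.integers(1, n)), replace=False))
            assert cross_connectivity(a, b, net) == brute_force_cross(a, b, net)

    def test_per_gene_counts_sum_to_total(self, rng):
        genes = [f"g{i}" for i in range(15)]
        net = nx.relabel_nodes(nx.gnp_random_graph(15, 0.3, seed=9),
                               dict(enumerate(genes)))
        a, b = set(genes[:5]), set(genes[4:9])
        per = per_gene_cross_edges(a, b, net)
        assert sum(per.values()) == cross_connectivity(a, b, net)


class TestPpiPermutation:
    def make_enriched(self):
        cand = [f"c{i}" for i in range(4)]
        ref = [f"r{i}" for i in range(6)]
        bg = cand + [f"n{i}" for i in range(40)]
        net = nx.Graph()
        net.add_nodes_from(bg + ref)
        for c in cand:
            for r in ref:
                net.add_edge(c, r)
        return cand, ref, bg, net

    def test_observed_above_all_permutations_reports_floor(self):
        cand, ref, bg, net = self.make_enriched()
        res = ppi_permutation_test(cand, ref, net, bg, 1000, seed=1)
        assert res.below_resolution
        assert res.p_value == 0.0
        assert res.p_report == "< 0.001"

    def test_background_equal_candidates_gives_p_one(self):
        cand, ref, _, net = self.make_enriched()
        res = ppi_permutation_test(cand, ref, net, cand, 200, seed=1)
        assert res.p_value == 1.0

    def test_candidates_must_be_in_background(self):
        cand, ref, bg, net = self.make_enriched()
        with pytest.raises(ParameterError):
            ppi_permutation_test(cand, ref, net, bg[1:], 100, seed=1)

    def test_matches_exhaustive_enumeration_small_background(self):
        # 6-gene background, 2 candidates: 15 possible permuted sets
        genes = [f"g{i}" for i in range(6)]
        ref = ["r0", "r1", "r2"]
        net = nx.Graph()
        net.add_nodes_from(genes + ref)
        rng = np.random.default_rng(7)
        for g in genes:
            for r in ref:
                if rng.random() < 0.5:
                    net.add_edge(g, r)
        cand = genes[:2]
        observed = cross_connectivity(cand, ref, net)
        stats = [
            brute_force_cross(set(pair), ref, net)
            for pair in itertools.combinations(genes, 2)
        ]
        exact_p = sum(s >= observed for s in stats) / len(stats)
        res = ppi_permutation_test(cand, ref, net, genes, 10000, seed=3)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_background_order_invariance(self):
        cand, ref, bg, net = self.make_enriched()
        a = ppi_permutation_test(cand, ref, net, bg, 300, seed=5)
        b = ppi_permutation_test(cand, ref, net, list(reversed(bg)), 300, seed=5)
        assert a.n_exceeding == b.n_exceeding

    def test_adding_cross_edge_monotone(self):
        cand = [f"c{i}" for i in range(3)]
        ref = [f"r{i}" for i in range(4)]
        bg = cand + [f"n{i}" for i in range(20)]
        net = nx.Graph()
        net.add_nodes_from(bg + ref)
        net.add_edge("c0", "r0")
        base = ppi_permutation_test(cand, ref, net, bg, 500, seed=2)
        net.add_edge("c1", "r1")
        more = ppi_permutation_test(cand, ref, net, bg, 500, seed=2)
        assert more.observed_statistic >= base.observed_statistic
        assert more.p_value <= base.p_value


class TestCoexpressionNetwork:
    def panel(self, values, genes):
        n = np.asarray(values).shape[1]
        return make_expression(np.asarray(values, dtype=float), genes,
                               ages=[100.0 + i for i in range(n)])

    def test_perfect_positive_and_negative_correlation(self):
        expr = self.panel([[1, 2, 3], [2, 4, 6], [3, 2, 1]], ["a", "b", "c"])
        cmap = {"PFC": "C"}
        net = coexpression_network(expr, "C", cmap, ["a"], ["b", "c"], 0.8)
        assert net.has_edge("a", "b")   # r = +1
        assert net.has_edge("a", "c")   # r = -1, absolute value rule

    def test_zero_variance_gene_excluded(self, caplog):
        expr = self.panel([[1, 2, 3], [5, 5, 5]], ["a", "flat"])
        with caplog.at_level("WARNING"):
            net = coexpression_network(expr, "C", {"PFC": "C"}, ["a"], ["flat"], 0.8)
        assert net.number_of_edges() == 0
        assert "zero-variance" in caplog.text

    def test_too_few_samples_rejected(self):
        expr = self.panel([[1, 2], [2, 1]], ["a", "b"])
        with pytest.raises(ValidationError, match=">= 3"):
            coexpression_network(expr, "C", {"PFC": "C"}, ["a"], ["b"], 0.8)

    def test_matches_bruteforce_all_pairs_scan(self, rng):
        genes = [f"g{i}" for i in range(4)]
        vals = rng.standard_normal((4, 8))
        expr = self.panel(vals, genes)
        thr = 0.3
        net = coexpression_network(expr, "C", {"PFC": "C"},
                                   genes[:2], genes[2:], thr)
        for g, h in itertools.product(genes[:2], genes[2:]):
            r = np.corrcoef(vals[genes.index(g)], vals[genes.index(h)])[0, 1]
            assert net.has_edge(g, h) == (abs(r) > thr)


class TestCoexpressionPermutation:
    def test_planted_block_detected(self, rng):
        # candidates and half the reference share a strong latent factor
        n_samples = 10
        latent = rng.standard_normal(n_samples)
        cand = [f"c{i}" for i in range(5)]
        ref = [f"r{i}" for i in range(10)]
        bg_noise = [f"n{i}" for i in range(60)]
        rows = []
        for g in cand + ref[:5]:
            rows.append(3.0 * latent + 0.3 * rng.standard_normal(n_samples))
        for g in ref[5:] + bg_noise:
            rows.append(rng.standard_normal(n_samples))
        expr = make_expression(np.array(rows), cand + ref + bg_noise,
                               ages=np.linspace(100, 900, n_samples))
        res = coexpression_permutation_test(
            expr, {"PFC": "C"}, cand, ref, cand + bg_noise,
            r_threshold=0.8, n_permutations=500, seed=4,
        )["C"]
        assert res.observed_statistic >= 20
        assert res.p_value < 0.01 or res.below_resolution

    def test_candidates_without_expression_rows_give_p_one(self, rng):
        genes = [f"n{i}" for i in range(10)]
        expr = make_expression(rng.standard_normal((10, 6)), genes,
                               ages=np.linspace(100, 900, 6))
        res = coexpression_permutation_test(
            expr, {"PFC": "C"}, ["absent1", "absent2"], ["n0"],
            ["absent1", "absent2"] + genes[1:],
            r_threshold=0.8, n_permutations=100, seed=0,
        )["C"]
        assert res.observed_statistic == 0
        assert res.p_value == 1.0
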