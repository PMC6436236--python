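"""Stouffer combination, permutation enrichment, tissue filter, communities."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from conftest import make_interactome
from gwasnet.apcst import run_rooted_ensemble
from gwasnet.enrichment import (
    GeneWisePvalues,
    TissueExpression,
    detect_communities,
    filter_by_expression,
    genes_in_windows,
    jaccard,
    permutation_test,
    stouffer_statistic,
)
from gwasnet.fixtures import FixtureConfig, simulate_genewise_pvalues


class TestStouffer:
    def test_median_p_gives_zero(self):
        k, zm = stouffer_statistic([0.5])
        assert (k, zm) == (1, pytest.approx(0.0, abs=1e-12))

    def test_four_equal_z_scores(self):
        p = 1 - 0.8413447460685429  # Phi(1)
        _, zm = stouffer_statistic([p] * 4)
        assert zm == pytest.approx(4 / np.sqrt(4), abs=1e-9)

    def test_against_high_precision_quantiles(self):
        _, zm = stouffer_statistic([0.01, 0.05, 0.5])
        expected = (ndtri(0.99) + ndtri(0.95) + 0.0) / np.sqrt(3)
        assert zm == pytest.approx(expected, abs=1e-9)
        assert zm == pytest.approx(2.2934, abs=1e-3)

    def test_boundary_pvalues_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, zm = stouffer_statistic([0.0, 0.5])
        assert np.isfinite(zm)

    def test_permutation_invariance_and_sqrt_scaling(self):
        p = [0.01, 0.2, 0.9]
        assert stouffer_statistic(p)[1] == pytest.approx(
            stouffer_statistic(p[::-1])[1]
        )
        _, z1 = stouffer_statistic([0.05])
        for k in (2, 4, 9):
            _, zk = stouffer_statistic([0.05] * k)
            assert zk == pytest.approx(z1 * np.sqrt(k), abs=1e-9)


@pytest.fixture(scope="module")
def world(planted_world):
    w = planted_world
    ens = run_rooted_ensemble(w["interactome"], w["prizes"], w["apcst_config"])
    return w, ens, sorted(ens.linking_nodes)


class TestPermutationTest:
    def test_window_exclusion_rule(self):
        gw = GeneWisePvalues(
            trait="t",
            pvalues={"A": 0.5, "B": 0.5},
            coordinates={"A": ("chr1", 400_000, 410_000), "B": ("chr2", 1, 10_000)},
            lead_snps=[("chr1", 900_000)],
        )
        assert genes_in_windows(gw, window_bp=1_000_000) == {"A"}
        assert genes_in_windows(gw, window_bp=100_000) == set()

    def test_null_pvalues_give_calibrated_rate(self, world):
        w, ens, linking = world
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            gw = simulate_genewise_pvalues(
                w["interactome"].nodes, enriched=set(), shift=0.0,
                seed=rep, config=w["config"],
            )
            res = permutation_test(ens, linking, gw, w["interactome"],
                                   n_perm=200, seed=rep)
            hits += res.p_nominal <= 0.05
        # ~5% +- binomial noise
        assert 1 <= hits <= 13

    def test_planted_shift_is_detected(self, world):
        w, ens, linking = world
        gw = simulate_genewise_pvalues(
            w["interactome"].nodes, enriched=set(linking), shift=1.5,
            seed=7, config=w["config"],
        )
        res = permutation_test(ens, linking, gw, w["interactome"],
                               n_perm=500, seed=7)
        assert res.p_nominal <= 0.05
        assert res.p_addone > 0
        assert res.k == len([g for g in linking if g in gw.pvalues])

    def test_window_genes_never_sampled(self, world):
        w, ens, linking = world
        gw = simulate_genewise_pvalues(
            w["interactome"].nodes, enriched=set(), shift=0.0,
            seed=3, config=w["config"],
        )
        excluded = genes_in_windows(gw, 1_000_000)
        assert excluded  # fixture plants lead SNPs inside gene bodies
        res = permutation_test(ens, linking, gw, w["interactome"],
                               n_perm=100, seed=3)
        assert res.n_excluded_window >= len(
            [g for g in excluded if g in w["interactome"].graph.nodes]
        ) > 0

    def test_small_n_perm_warns(self, world):
        w, ens, linking = world
        gw = simulate_genewise_pvalues(
            w["interactome"].nodes, enriched=set(), shift=0.0,
            seed=9, config=w["config"],
        )
        with pytest.warns(UserWarning, match="unstable"):
            permutation_test(ens, linking, gw, w["interactome"], n_perm=50, seed=9)


class TestExpressionFilter:
    def _expr(self, data, samples=4):
        return TissueExpression(
            tissue="islet",
            matrix=pd.DataFrame(
                data, columns=[f"s{i}" for i in range(samples)]
            ).astype(float),
        )

    def _net(self, *nodes):
        g = nx.Graph()
        g.add_edges_from(zip(nodes[:-1], nodes[1:]))
        return g

    def test_majority_low_gene_removed(self):
        expr = self._expr({"A": [0.05, 0.05, 0.05, 5.0], "B": [1, 1, 1, 1]}.values())
        expr.matrix.index = ["A", "B"]
        net = self._net("A", "B")
        out = filter_by_expression(net, expr)
        assert set(out.nodes) == {"B"}

    def test_exactly_half_low_is_retained(self):
        expr = self._expr({"A": [0.05, 0.05, 5.0, 5.0], "B": [1, 1, 1, 1]}.values())
        expr.matrix.index = ["A", "B"]
        out = filter_by_expression(self._net("A", "B"), expr)
        assert set(out.nodes) == {"A", "B"}

    def test_fully_expressed_network_unchanged(self):
        expr = self._expr({"A": [1, 2, 3, 4], "B": [5, 6, 7, 8]}.values())
        expr.matrix.index = ["A", "B"]
        net = self._net("A", "B")
        out = filter_by_expression(net, expr)
        assert set(out.nodes) == set(net.nodes)
        assert set(out.edges) == set(net.edges)

    def test_idempotent_and_antimonotone_in_threshold(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        matrix = pd.DataFrame(rng.exponential(0.3, size=(20, 6)), index=genes)
        expr = TissueExpression(tissue="t", matrix=matrix)
        g = nx.path_graph(genes)
        once = filter_by_expression(g, expr)
        twice = filter_by_expression(once, expr)
        assert set(once.nodes) == set(twice.nodes)
        lo = filter_by_expression(g, expr, tpm_threshold=0.05)
        hi = filter_by_expression(g, expr, tpm_threshold=0.4)
        assert set(hi.nodes) <= set(lo.nodes)

    def test_uncovered_genes_retained_with_warning(self):
        expr = self._expr({"A": [1, 1, 1, 1]}.values())
        expr.matrix.index = ["A"]
        with pytest.warns(UserWarning, match="absent"):
            out = filter_by_expression(self._net("A", "B"), expr)
        assert "B" in out.nodes


class TestJaccard:
    def test_identical_disjoint_partial(self):
        assert jaccard({"A", "B"}, {"A", "B"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = set(rng.choice(20, size=rng.integers(1, 10), replace=False).tolist())
            b = set(rng.choice(20, size=rng.integers(1, 10), replace=False).tolist())
            j = jaccard(a, b)
            assert j == jaccard(b, a)
            assert 0 <= j <= 1
            assert (j == 1.0) == (a == b)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())


class TestCommunities:
    def test_disjoint_triangles_are_two_communities(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        part = detect_communities(g)
        assert len(set(part.communities.values())) == 2
        assert part.communities["a"] == part.communities["b"] == part.communities["c"]

    def test_two_cliques_with_bridge_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        part = detect_communities(g)
        assert len({part.communities[n] for n in (0, 1, 2, 3)}) == 1
        assert len({part.communities[n] for n in (4, 5, 6, 7)}) == 1
        assert part.communities[0] != part.communities[4]

    def test_modularity_matches_direct_formula(self):
        g = nx.karate_club_graph()
        part = detect_communities(g)
        comms = {}
        for node, cid in part.communities.items():
            comms.setdefault(cid, set()).add(node)
        q = nx.community.modularity(g, list(comms.values()))
        assert part.modularity == pytest.approx(q, abs=1e-12)
        assert set(part.communities) == set(g.nodes)
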