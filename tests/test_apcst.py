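"""Interactome loading, APCST solvers, ensemble assembly and specificity.

The brute-force oracle used here enumerates node subsets (via networkx
connectivity and MST) and, on the smallest graphs, all spanning trees of
every connected subset — an independent code path from the solver.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_interactome, random_instance
from gwasnet.apcst import (
    ApcstConfig,
    PrizeMap,
    build_ensemble,
    degree_matched_sample,
    load_interactome,
    solve_apcst_exact,
    solve_apcst_heuristic,
    sweep_beta,
)


def brute_force_best(inter, prizes, beta, root):
    """Best objective over all connected subsets containing the root."""
    nodes = sorted(inter.graph.nodes)
    best = -math.inf
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if root not in sub:
                continue
            sg = inter.graph.subgraph(sub)
            if not nx.is_connected(sg):
                continue
            mst = sum(
                d["cost"]
                for _, _, d in nx.minimum_spanning_tree(sg, weight="cost").edges(data=True)
            )
            best = max(best, beta * sum(prizes.get(x) for x in sub) - mst)
    return best


class TestLoadInteractome:
    def test_confidence_boundary_is_strict(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "node_a\tnode_b\tconfidence\nA\tB\t0.124\nB\tC\t0.125\nC\tD\t0.9\n"
        )
        inter = load_interactome(path)
        assert not inter.graph.has_edge("A", "B")
        assert inter.graph.has_edge("B", "C")

    def test_full_confidence_edge_has_zero_cost(self):
        inter = load_interactome([("A", "B", 1.0)])
        assert inter.cost("A", "B") == 0.0

    def test_duplicates_collapse_to_max_confidence(self):
        inter = load_interactome([("A", "B", 0.3), ("B", "A", 0.5)])
        assert inter.graph.edges["A", "B"]["confidence"] == 0.5

    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            inter = load_interactome([("A", "A", 0.9), ("A", "B", 0.9)])
        assert inter.graph.number_of_edges() == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\t0.5\nA\tC\n")
        with pytest.raises(ValueError, match=":2"):
            load_interactome(path)


class TestExactSolver:
    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node("A")
        from gwasnet.apcst import Interactome

        inter = Interactome(graph=g)
        sol = solve_apcst_exact(inter, PrizeMap(prizes={"A": 1.0}),
                                ApcstConfig(beta=8.0, root="A"))
        assert sol.nodes == {"A"} and sol.objective == pytest.approx(8.0)

    def test_path_collects_both_prizes_at_moderate_beta(self, path_interactome):
        inter, prizes = path_interactome
        sol = solve_apcst_exact(inter, prizes, ApcstConfig(beta=2.0, root="A"))
        assert sol.nodes == {"A", "B", "C"}
        assert sol.objective == pytest.approx(2 * 2 - 1.0)

    def test_path_degenerates_to_single_node_at_tiny_beta(self, path_interactome):
        inter, prizes = path_interactome
        sol = solve_apcst_exact(inter, prizes, ApcstConfig(beta=0.2, root="A"))
        assert sol.nodes == {"A"}
        assert sol.objective == pytest.approx(0.2)

    def test_matches_all_subtree_enumeration_on_tiny_graphs(self):
        """Exhaustive spanning-tree enumeration confirms the MST reduction."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            inter, prizes = random_instance(6, 0.5, rng)
            best = -math.inf
            nodes = sorted(inter.graph.nodes)
            for r in range(1, 7):
                for sub in itertools.combinations(nodes, r):
                    if nodes[0] not in sub:
                        continue
                    sg = inter.graph.subgraph(sub)
                    if not nx.is_connected(sg):
                        continue
                    psum = 2.0 * sum(prizes.get(x) for x in sub)
                    if r == 1:
                        best = max(best, psum)
                        continue
                    for tree in nx.SpanningTreeIterator(nx.Graph(sg), weight="cost"):
                        cost = sum(d["cost"] for _, _, d in tree.edges(data=True))
                        best = max(best, psum - cost)
                        break  # iterator is cost-ordered: first tree is the MST
            sol = solve_apcst_exact(inter, prizes, ApcstConfig(beta=2.0, root=nodes[0]))
            assert sol.objective == pytest.approx(best, abs=1e-9)

    def test_solution_is_tree_with_consistent_objective(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            inter, prizes = random_instance(8, 0.4, rng)
            cfg = ApcstConfig(beta=2.0, root="n00")
            sol = solve_apcst_exact(inter, prizes, cfg)
            tg = nx.Graph(list(sol.edges))
            tg.add_nodes_from(sol.nodes)
            assert nx.is_tree(tg)
            assert "n00" in sol.nodes
            assert sol.recompute_objective(inter, prizes, 2.0) == pytest.approx(
                sol.objective, abs=1e-12
            )

    def test_root_missing_and_size_limit_errors(self, path_interactome):
        inter, prizes = path_interactome
        with pytest.raises(ValueError, match="root"):
            solve_apcst_exact(inter, prizes, ApcstConfig(root="Z"))
        with pytest.raises(ValueError, match="use heuristic"):
            solve_apcst_exact(inter, prizes, ApcstConfig(root="A", exact_size_limit=2))


class TestHeuristicSolver:
    def test_never_beats_exact_and_never_worse_than_root_only(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            inter, prizes = random_instance(10, 0.35, rng)
            for beta in (0.5, 2.0, 8.0):
                cfg = ApcstConfig(beta=beta, root="n00")
                h = solve_apcst_heuristic(inter, prizes, cfg)
                e = solve_apcst_exact(inter, prizes, cfg)
                assert h.objective <= e.objective + 1e-9
                assert h.objective >= beta * prizes.get("n00") - 1e-9
                assert not h.optimal_flag and e.optimal_flag

    def test_root_only_fallback_when_expansion_unprofitable(self):
        inter = make_interactome([("A", "B", 0.9)])
        prizes = PrizeMap(prizes={"A": 1.0, "B": 0.05})
        sol = solve_apcst_heuristic(inter, prizes, ApcstConfig(beta=1.0, root="A"))
        assert sol.nodes == {"A"}
        assert sol.objective == pytest.approx(1.0)

    def test_deterministic(self, planted_world):
        w = planted_world
        cfg = ApcstConfig(beta=8.0, root=w["seeds"][0])
        s1 = solve_apcst_heuristic(w["interactome"], w["prizes"], cfg)
        s2 = solve_apcst_heuristic(w["interactome"], w["prizes"], cfg)
        assert s1.nodes == s2.nodes and s1.objective == s2.objective


class TestEnsemble:
    def _sol(self, nodes, edges=()):
        from gwasnet.apcst import _solution

        return _solution(nodes, edges, 0.0, False, None)

    def test_union_is_idempotent_and_reprojected(self):
        inter = make_interactome([("A", "B", 0.1), ("B", "C", 0.1), ("A", "C", 0.1)])
        runs = [self._sol({"A", "B"}, [("A", "B")]), self._sol({"B", "C"}, [("B", "C")])]
        ens = build_ensemble(runs, inter, seeds={"A"}, min_network_size=1)
        assert set(ens.graph.nodes) == {"A", "B", "C"}
        assert ens.graph.has_edge("A", "C")  # recovered by reprojection

    def test_size_threshold_is_strict(self):
        inter = make_interactome(
            [(f"x{i}", f"x{i+1}", 0.1) for i in range(10)]
        )
        run10 = self._sol({f"x{i}" for i in range(10)},
                          [(f"x{i}", f"x{i+1}") for i in range(9)])
        with pytest.raises(ValueError, match="no networks above size threshold"):
            build_ensemble([run10], inter, seeds=set(), min_network_size=10)
        run11 = self._sol({f"x{i}" for i in range(11)},
                          [(f"x{i}", f"x{i+1}") for i in range(10)])
        ens = build_ensemble([run10, run11], inter, seeds={"x0"}, min_network_size=10)
        assert ens.contributing_runs == 1

    def test_labels_partition_nodes(self, planted_world):
        from gwasnet.apcst import run_rooted_ensemble

        w = planted_world
        ens = run_rooted_ensemble(w["interactome"], w["prizes"], w["apcst_config"])
        assert ens.seed_nodes | ens.linking_nodes == set(ens.graph.nodes)
        assert not ens.seed_nodes & ens.linking_nodes
        for a, b in ens.graph.edges:
            assert w["interactome"].graph.has_edge(a, b)


class TestDegreeMatchedSampling:
    def test_sample_matches_log_bins(self):
        rng = np.random.default_rng(3)
        degrees = {f"n{i}": d for i, d in enumerate([1, 1, 2, 3, 4, 6, 8, 15, 16, 40])}
        targets = [1, 3, 8]
        sample = degree_matched_sample(degrees, targets, rng)
        assert len(sample) == len(set(sample)) == 3
        got_bins = sorted(int(degrees[s]).bit_length() for s in sample)
        assert got_bins == sorted(int(t).bit_length() for t in targets)

    def test_bin_widening_warns(self):
        rng = np.random.default_rng(4)
        degrees = {"a": 1, "b": 64, "c": 64, "d": 64}
        with pytest.warns(UserWarning, match="widened"):
            sample = degree_matched_sample(degrees, [1, 1], rng)
        assert len(sample) == 2


def test_sweep_beta_sizes_weakly_increase(planted_world):
    w = planted_world
    table = sweep_beta(w["interactome"], w["prizes"], betas=[0.5, 4, 8, 30],
                       config=w["apcst_config"])
    sizes = table["ensemble_size"].tolist()
    assert sizes[0] <= sizes[-1]
    assert table["seed_fraction"].iloc[-1] >= 0.25
    assert set(table.columns) == {"beta", "ensemble_size", "seed_fraction"}
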