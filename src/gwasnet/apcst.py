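"""Asymmetric prize-collecting Steiner tree (APCST) analysis of interactomes.

Given a confidence-weighted protein-protein interaction graph G = (V, A)
with arc costs c >= 0, node prizes p >= 0 (the PCS of seed genes, zero
elsewhere) and a root terminal, the rooted APCST seeks a tree
S = (V_s, A_s) containing the root that maximises

    P(S) = beta * sum_{i in V_s} p_i  -  sum_{(i,j) in A_s} c_ij.

beta trades prize collection against edge cost and thereby controls
network size. Each undirected PPI edge is treated as two antiparallel
arcs of equal cost, so solutions are reported as undirected trees.

Two solvers are provided: an exact one for small instances (exhaustive
search over connected node subsets, using the fact that the optimal tree
on a fixed node set is the minimum spanning tree of the induced
subgraph) and a fast greedy heuristic (repeated best-gain shortest-path
expansion from the root, followed by pruning of unprofitable leaves).

One rooted run per seed gene is performed; runs yielding more than
``min_network_size`` nodes are united into an ensemble network which is
reprojected onto the interactome to recover edges between nodes drawn
from different runs. Node specificity is assessed by repeating the whole
procedure with degree-matched random seed sets.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_CONFIDENCE_THRESHOLD = 0.124


# ---------------------------------------------------------------------------
# Interactome


@dataclass
class Interactome:
    """Undirected confidence-weighted PPI graph with derived arc costs."""

    graph: nx.Graph
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    _index: dict | None = field(default=None, repr=False)
    _adj: list | None = field(default=None, repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def cost(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["cost"]

    def _adjacency(self) -> tuple[dict, list, list]:
        """(node -> index, index -> node, adjacency list of (j, cost))."""
        if self._index is None:
            order = self.nodes
            index = {n: i for i, n in enumerate(order)}
            adj: list[list[tuple[int, float]]] = [[] for _ in order]
            for a, b, d in self.graph.edges(data=True):
                ia, ib = index[a], index[b]
                adj[ia].append((ib, d["cost"]))
                adj[ib].append((ia, d["cost"]))
            self._index = index
            self._adj = adj
        return self._index, self.nodes, self._adj


def load_interactome(
    edge_list,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    cost_rule: str = "one_minus_confidence",
    uniform_cost: float = 1.0,
) -> Interactome:
    """Build an interactome from an edge list, applying the confidence filter.

    ``edge_list`` is a path to a TSV (node_a, node_b, confidence; header
    optional) or an iterable of (a, b, confidence) triples. Edges with
    confidence <= threshold are removed (strict ``>`` retention);
    duplicates collapse to the maximum confidence; self-loops are dropped
    with a warning. Arc cost is 1 - confidence by default, or a constant
    under ``cost_rule="uniform"``.
    """
    if cost_rule not in ("one_minus_confidence", "uniform"):
        raise ValueError(f"unknown cost rule {cost_rule!r}")

    import os

    if isinstance(edge_list, (str, bytes, os.PathLike)):
        triples = _parse_edge_file(edge_list)
    else:
        triples = list(edge_list)

    g = nx.Graph()
    n_self = 0
    for a, b, conf in triples:
        conf = float(conf)
        if not 0 < conf <= 1:
            raise ValueError(f"confidence {conf} for edge {a}-{b} outside (0, 1]")
        if a == b:
            n_self += 1
            continue
        if conf <= confidence_threshold:
            continue
        if g.has_edge(a, b):
            conf = max(conf, g.edges[a, b]["confidence"])
        cost = uniform_cost if cost_rule == "uniform" else 1.0 - conf
        g.add_edge(a, b, confidence=conf, cost=cost)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edge(s)", stacklevel=2)
    return Interactome(graph=g, confidence_threshold=confidence_threshold)


def _parse_edge_file(path) -> list[tuple[str, str, float]]:
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, conf = parts[0], parts[1], parts[2]
            if lineno == 1 and conf.lower() in ("confidence", "score", "weight"):
                continue  # header row
            try:
                triples.append((a, b, float(conf)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad confidence {conf!r}") from exc
    return triples


# ---------------------------------------------------------------------------
# Configuration / solution containers


@dataclass
class PrizeMap:
    """Non-negative node prizes with the fixed-terminal (seed) set."""

    prizes: dict[str, float]
    terminals: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if any(p < 0 for p in self.prizes.values()):
            raise ValueError("prizes must be non-negative")
        if self.terminals is None:
            self.terminals = frozenset(self.prizes)
        else:
            self.terminals = frozenset(self.terminals)

    def get(self, node: str) -> float:
        return self.prizes.get(node, 0.0)


@dataclass
class ApcstConfig:
    beta: float = 8.0
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    min_network_size: int = 10
    root: str | None = None
    solver: str = "heuristic"  # "exact" | "heuristic"
    seed: int = 0
    exact_size_limit: int = 18


@dataclass
class SteinerSolution:
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    objective: float
    optimal_flag: bool
    root: str | None = None

    def recompute_objective(self, interactome: Interactome, prizes: PrizeMap, beta: float) -> float:
        return beta * sum(prizes.get(n) for n in self.nodes) - sum(
            interactome.cost(a, b) for a, b in self.edges
        )


def _solution(nodes, edges, objective, optimal, root) -> SteinerSolution:
    return SteinerSolution(
        nodes=frozenset(nodes),
        edges=frozenset(tuple(sorted(e)) for e in edges),
        objective=float(objective),
        optimal_flag=optimal,
        root=root,
    )


# ---------------------------------------------------------------------------
# Exact solver (small instances)


def solve_apcst_exact(
    interactome: Interactome, prizes: PrizeMap, config: ApcstConfig
) -> SteinerSolution:
    """Provably optimal APCST by exhaustive search over node subsets.

    For a fixed connected node set the cheapest spanning tree is the MST
    of the induced subgraph, so it suffices to enumerate connected
    subsets (containing the root, in rooted mode) and take the best
    ``beta * sum(prizes) - MST cost``. Exponential in |V|; guarded by
    ``config.exact_size_limit``.
    """
    index, order, adj = interactome._adjacency()
    n = len(order)
    if n == 0:
        raise ValueError("empty interactome")
    if n > config.exact_size_limit:
        raise ValueError(
            f"instance has {n} nodes > exact_size_limit={config.exact_size_limit}; "
            "use heuristic"
        )
    root_idx = None
    if config.root is not None:
        if config.root not in index:
            raise ValueError(f"root {config.root!r} not in interactome")
        root_idx = index[config.root]

    prize = [prizes.get(node) for node in order]
    nbr_mask = [0] * n
    cost = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        for j, c in adj[i]:
            nbr_mask[i] |= 1 << j
            if c < cost[i][j]:
                cost[i][j] = c
                cost[j][i] = c

    beta = config.beta
    best_obj = -math.inf
    best_mask = 0

    if root_idx is not None:
        root_bit = 1 << root_idx
        others = [i for i in range(n) if i != root_idx]
        n_sub = 1 << len(others)
        submasks = (
            root_bit | sum(1 << others[k] for k in range(len(others)) if sub >> k & 1)
            for sub in range(n_sub)
        )
    else:
        submasks = (m for m in range(1, 1 << n))

    for mask in submasks:
        start = mask & -mask if root_idx is None else 1 << root_idx
        # connectivity by bitmask BFS
        reach = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                nxt |= nbr_mask[b.bit_length() - 1]
                m ^= b
            frontier = nxt & mask & ~reach
            reach |= frontier
        if reach != mask:
            continue
        members = []
        m = mask
        psum = 0.0
        while m:
            b = m & -m
            i = b.bit_length() - 1
            members.append(i)
            psum += prize[i]
            m ^= b
        mst = _prim_cost(members, cost)
        obj = beta * psum - mst
        if obj > best_obj + 1e-15 or (obj > best_obj - 1e-15 and mask < best_mask):
            best_obj = obj
            best_mask = mask

    members = [i for i in range(n) if best_mask >> i & 1]
    edges = _prim_edges(members, cost)
    nodes = [order[i] for i in members]
    return _solution(
        nodes,
        [(order[i], order[j]) for i, j in edges],
        best_obj,
        True,
        config.root,
    )


def _prim_cost(members: list[int], cost: list[list[float]]) -> float:
    k = len(members)
    if k <= 1:
        return 0.0
    in_tree = [False] * k
    dist = [math.inf] * k
    dist[0] = 0.0
    total = 0.0
    for _ in range(k):
        best, bd = -1, math.inf
        for t in range(k):
            if not in_tree[t] and dist[t] < bd:
                best, bd = t, dist[t]
        in_tree[best] = True
        total += bd
        row = cost[members[best]]
        for t in range(k):
            if not in_tree[t]:
                c = row[members[t]]
                if c < dist[t]:
                    dist[t] = c
    return total


def _prim_edges(members: list[int], cost: list[list[float]]) -> list[tuple[int, int]]:
    k = len(members)
    if k <= 1:
        return []
    in_tree = [False] * k
    dist = [math.inf] * k
    parent = [-1] * k
    dist[0] = 0.0
    edges = []
    for _ in range(k):
        best, bd = -1, math.inf
        for t in range(k):
            if not in_tree[t] and dist[t] < bd:
                best, bd = t, dist[t]
        in_tree[best] = True
        if parent[best] >= 0:
            edges.append((members[parent[best]], members[best]))
        row = cost[members[best]]
        for t in range(k):
            if not in_tree[t] and row[members[t]] < dist[t]:
                dist[t] = row[members[t]]
                parent[t] = best
    return edges


# ---------------------------------------------------------------------------
# Heuristic solver


def solve_apcst_heuristic(
    interactome: Interactome, prizes: PrizeMap, config: ApcstConfig
) -> SteinerSolution:
    """Greedy best-gain path expansion from the root, plus local search.

    Growth phase: repeatedly run a multi-source shortest-path (on arc
    cost) from the current tree, evaluate for every prize-bearing node
    the gain ``beta * (prizes newly collected along the path) - path
    cost`` and graft the best strictly positive path. The selected node
    set is then locally optimised: its tree is re-derived as the MST of
    the induced subgraph, unprofitable leaves are pruned, and single
    nodes are added or removed while the objective improves. Feasible
    (never worse than the root-only tree) and deterministic.
    """
    index, order, adj = interactome._adjacency()
    root = config.root
    if root is None:
        root = max(prizes.prizes, key=lambda g: (prizes.get(g), g), default=None)
        if root is None or root not in index:
            raise ValueError("no root given and no prize node in the interactome")
    elif root not in index:
        raise ValueError(f"root {root!r} not in interactome")
    beta = config.beta

    r = index[root]
    n = len(order)
    prize = np.array([prizes.get(node) for node in order])
    targets = [i for i in range(n) if prize[i] > 0 and i != r]

    vs: set[int] = {r}
    for _ in range(n):  # alternate growth and local search to a fixpoint
        grew = _expand_paths(vs, adj, prize, beta, targets)
        improved = _local_search(vs, adj, prize, beta, r)
        if not grew and not improved:
            break

    edges = _mst_edges(vs, adj)
    obj = beta * float(sum(prize[i] for i in vs)) - sum(c for _, _, c in edges)
    return _solution(
        [order[i] for i in sorted(vs)],
        [(order[a], order[b]) for a, b, _ in edges],
        obj,
        False,
        root,
    )


def _expand_paths(vs: set[int], adj, prize, beta: float, targets) -> bool:
    """Graft best positive-gain shortest-cost paths onto the node set."""
    grew = False
    while True:
        dist, pred = _multisource_dijkstra(len(adj), adj, sorted(vs))
        best_gain = 1e-12
        best_target = -1
        for v in targets:
            if v in vs or not math.isfinite(dist[v]):
                continue
            psum = 0.0
            u = v
            while u not in vs:
                psum += prize[u]
                u = pred[u]
            gain = beta * psum - dist[v]
            if gain > best_gain:
                best_gain = gain
                best_target = v
        if best_target < 0:
            return grew
        u = best_target
        while u not in vs:
            vs.add(u)
            u = pred[u]
        grew = True


def _local_search(vs: set[int], adj, prize, beta: float, root: int) -> bool:
    """Single-node add/remove moves on the induced-subgraph MST."""
    improved = False
    for _ in range(4 * len(adj)):
        base_cost = _mst_cost(vs, adj)
        # best single-node addition (exact MST delta)
        best_add, best_add_gain = -1, 1e-12
        candidates = sorted(
            {j for i in vs for j, _ in adj[i] if j not in vs}
        )
        for v in candidates:
            new_cost = _mst_cost(vs | {v}, adj)
            gain = beta * prize[v] - (new_cost - base_cost)
            if gain > best_add_gain:
                best_add_gain, best_add = gain, v
        # best single-node removal (must keep the root and connectivity)
        best_rm, best_rm_gain = -1, 1e-12
        for v in sorted(vs):
            if v == root:
                continue
            rest = vs - {v}
            if not _is_connected(rest, adj, root):
                continue
            gain = (base_cost - _mst_cost(rest, adj)) - beta * prize[v]
            if gain > best_rm_gain:
                best_rm_gain, best_rm = gain, v
        if best_add_gain >= best_rm_gain and best_add >= 0:
            vs.add(best_add)
        elif best_rm >= 0:
            vs.discard(best_rm)
        else:
            return improved
        improved = True
    return improved


def _mst_cost(vs: set[int], adj) -> float:
    return sum(c for _, _, c in _mst_edges(vs, adj))


def _mst_edges(vs: set[int], adj) -> list[tuple[int, int, float]]:
    """Prim's MST of the induced subgraph (assumes vs is connected)."""
    if len(vs) <= 1:
        return []
    start = next(iter(vs))
    in_tree = {start}
    heap = [(c, start, j) for j, c in adj[start] if j in vs]
    heapq.heapify(heap)
    edges = []
    while heap and len(in_tree) < len(vs):
        c, a, b = heapq.heappop(heap)
        if b in in_tree:
            continue
        in_tree.add(b)
        edges.append((a, b, c))
        for j, cj in adj[b]:
            if j in vs and j not in in_tree:
                heapq.heappush(heap, (cj, b, j))
    if len(in_tree) < len(vs):
        raise ValueError("node set not connected")
    return edges


def _is_connected(vs: set[int], adj, start: int) -> bool:
    if start not in vs:
        return False
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for j, _ in adj[u]:
            if j in vs and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(vs)


def _multisource_dijkstra(n: int, adj, sources: list[int]):
    dist = [math.inf] * n
    pred = [-1] * n
    heap = []
    for s in sources:
        dist[s] = 0.0
        heap.append((0.0, s))
    heapq.heapify(heap)
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, c in adj[u]:
            nd = d + c
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def solve_apcst(
    interactome: Interactome, prizes: PrizeMap, config: ApcstConfig
) -> SteinerSolution:
    if config.solver == "exact":
        return solve_apcst_exact(interactome, prizes, config)
    if config.solver == "heuristic":
        return solve_apcst_heuristic(interactome, prizes, config)
    raise ValueError(f"unknown solver {config.solver!r}")


# ---------------------------------------------------------------------------
# Ensemble assembly


@dataclass
class EnsembleNetwork:
    """Union of retained rooted runs, reprojected onto the interactome."""

    graph: nx.Graph  # nodes carry a "label" attribute: "seed" | "linking"
    contributing_runs: int

    @property
    def seed_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["label"] == "seed"}

    @property
    def linking_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["label"] == "linking"}


def build_ensemble(
    solutions: Sequence[SteinerSolution],
    interactome: Interactome,
    seeds: Iterable[str],
    min_network_size: int = 10,
) -> EnsembleNetwork:
    """Union of runs larger than ``min_network_size`` nodes (strict >),
    reprojected onto the interactome (all interactome edges among the
    union's nodes are restored). Nodes are labelled seed or linking."""
    retained = [s for s in solutions if len(s.nodes) > min_network_size]
    if not retained:
        raise ValueError("no networks above size threshold")
    union: set[str] = set()
    for s in retained:
        union |= s.nodes
    seeds = set(seeds)
    g = interactome.graph.subgraph(union).copy()
    g.add_nodes_from(union - set(g.nodes))
    for node in g.nodes:
        g.nodes[node]["label"] = "seed" if node in seeds else "linking"
    return EnsembleNetwork(graph=g, contributing_runs=len(retained))


def run_rooted_ensemble(
    interactome: Interactome,
    prizes: PrizeMap,
    config: ApcstConfig,
    min_network_size: int | None = None,
    allow_empty: bool = False,
) -> EnsembleNetwork | None:
    """One rooted run per seed terminal, combined into the ensemble.

    Seeds absent from the interactome are skipped. Returns None instead
    of raising when ``allow_empty`` and no run passes the size filter.
    """
    if min_network_size is None:
        min_network_size = config.min_network_size
    index, _, _ = interactome._adjacency()
    mapped = sorted(t for t in prizes.terminals if t in index)
    solutions = []
    for seed_node in mapped:
        cfg = replace(config, root=seed_node)
        solutions.append(solve_apcst(interactome, prizes, cfg))
    retained = [s for s in solutions if len(s.nodes) > min_network_size]
    if not retained and allow_empty:
        return None
    return build_ensemble(solutions, interactome, prizes.terminals, min_network_size)


# ---------------------------------------------------------------------------
# Degree-matched sampling (shared with the enrichment permutation test)


def degree_matched_sample(
    degrees: Mapping[str, int],
    target_degrees: Sequence[int],
    rng: np.random.Generator,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Sample len(target_degrees) distinct nodes matching the target
    degree distribution within logarithmic (base-2) degree bins.

    Bins short of candidates are widened symmetrically (with a warning)
    until they can supply the requested count.
    """
    exclude = set(exclude)
    by_bin: dict[int, list[str]] = {}
    for node in sorted(degrees):
        if node in exclude:
            continue
        by_bin.setdefault(_log_bin(degrees[node]), []).append(node)

    needed: dict[int, int] = {}
    for d in target_degrees:
        b = _log_bin(d)
        needed[b] = needed.get(b, 0) + 1

    chosen: list[str] = []
    used: set[str] = set()
    for b in sorted(needed):
        count = needed[b]
        width = 0
        while True:
            cands = [
                v
                for bb in range(b - width, b + width + 1)
                for v in by_bin.get(bb, [])
                if v not in used
            ]
            if len(cands) >= count:
                break
            width += 1
            if width > 64:
                raise ValueError("cannot satisfy degree-matched sample")
        if width > 0:
            warnings.warn(
                f"degree bin {b} widened by +/-{width} to find {count} candidates",
                stacklevel=2,
            )
        pick = rng.choice(len(cands), size=count, replace=False)
        for i in pick:
            chosen.append(cands[i])
            used.add(cands[i])
    return chosen


def _log_bin(degree: int) -> int:
    return int(degree).bit_length()  # 0 -> 0, 1 -> 1, 2-3 -> 2, 4-7 -> 3, ...


# ---------------------------------------------------------------------------
# Specificity against random seed sets


@dataclass
class SpecificityReport:
    specificity: dict[str, float]  # node -> 1 - appearance fraction
    n_random_runs: int


def assess_specificity(
    ensemble: EnsembleNetwork,
    interactome: Interactome,
    prizes: PrizeMap,
    config: ApcstConfig,
    n_random: int = 100,
    nodes: Iterable[str] | None = None,
) -> SpecificityReport:
    """Node specificity = 1 - fraction of degree-matched random-seed
    ensembles (same parameters, same prize multiset randomly reassigned)
    that contain the node. ``nodes`` restricts/extends the scored set
    (default: all ensemble nodes)."""
    rng = np.random.default_rng(config.seed)
    index, _, _ = interactome._adjacency()
    real_seeds = sorted(t for t in prizes.terminals if t in index)
    target_degrees = [interactome.degree(s) for s in real_seeds]
    prize_values = [prizes.get(s) for s in real_seeds]
    degrees = {n: interactome.degree(n) for n in interactome.nodes}

    scored = list(nodes) if nodes is not None else list(ensemble.graph.nodes)
    counts = {node: 0 for node in scored}
    for _ in range(n_random):
        random_seeds = degree_matched_sample(degrees, target_degrees, rng)
        assignment = rng.permutation(len(prize_values))
        random_prizes = PrizeMap(
            prizes={s: prize_values[assignment[i]] for i, s in enumerate(random_seeds)},
            terminals=frozenset(random_seeds),
        )
        random_ensemble = run_rooted_ensemble(
            interactome, random_prizes, config, allow_empty=True
        )
        if random_ensemble is None:
            continue
        present = set(random_ensemble.graph.nodes)
        for node in counts:
            if node in present:
                counts[node] += 1
    spec = {node: 1.0 - c / n_random for node, c in counts.items()}
    return SpecificityReport(specificity=spec, n_random_runs=n_random)


# ---------------------------------------------------------------------------
# Beta sweep


def sweep_beta(
    interactome: Interactome,
    prizes: PrizeMap,
    betas: Sequence[float] = tuple(range(4, 31, 2)),
    config: ApcstConfig | None = None,
) -> pd.DataFrame:
    """Ensemble size and seed inclusion across beta values (default 4-30)."""
    config = config or ApcstConfig()
    rows = []
    n_seeds = max(len(prizes.terminals), 1)
    for beta in betas:
        if beta <= 0:
            raise ValueError("beta must be positive")
        cfg = replace(config, beta=float(beta))
        ensemble = run_rooted_ensemble(interactome, prizes, cfg, allow_empty=True)
        if ensemble is None:
            size, frac = 0, 0.0
        else:
            size = ensemble.graph.number_of_nodes()
            frac = len(ensemble.seed_nodes & set(prizes.terminals)) / n_seeds
        rows.append({"beta": float(beta), "ensemble_size": size, "seed_fraction": frac})
    return pd.DataFrame(rows)
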