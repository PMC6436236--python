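"""Association enrichment of network nodes, tissue filtering, communities.

Linking (Steiner) nodes enter the network purely to connect seed genes,
so independent association signal among them is evidence that the
network captures trait biology rather than interactome topology. Each
linking node's gene-wise association p-value is converted to a Z score,
Z_i = Phi^-1(1 - p_i), and combined with Stouffer's method,
Zm = sum(Z_i) / sqrt(k). The null distribution of Zm is obtained by node
permutation: each permutation replaces the linking nodes with a
degree-matched (log-binned) random set drawn from the interactome,
excluding genes within a window (default 1 Mb) of any lead SNP of the
trait, and the nominal p-value is the fraction of permuted Zm strictly
exceeding the observed one.

The module also hosts the tissue-expression node filter (TPM rule), the
Jaccard similarity of networks, and modularity-based community
decomposition of the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import ndtri

from .apcst import Interactome, _log_bin

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class GeneWisePvalues:
    """Gene-wise association p-values for one trait, with gene coordinates
    and the trait's lead SNPs (both needed for the exclusion windows)."""

    trait: str
    pvalues: dict[str, float]
    coordinates: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    lead_snps: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    trait: str
    k: int
    zm_observed: float
    permutation_zms: np.ndarray
    p_nominal: float  # #(permuted Zm > observed) / n_perm (strict >)
    p_addone: float  # (r + 1) / (n + 1), never exactly zero
    n_perm: int
    n_unscored: int  # linking nodes without a gene-wise p-value
    n_excluded_window: int  # pool genes removed by the lead-SNP windows


def stouffer_statistic(pvalues: Iterable[float]) -> tuple[int, float]:
    """Stouffer combination: (k, Zm) with Zm = sum(Phi^-1(1 - p)) / sqrt(k).

    Boundary p-values (0 or 1) are clamped into the open interval with a
    warning rather than producing infinite Z scores.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("stouffer_statistic requires at least one p-value")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at 0 or 1 clamped into (0, 1)", stacklevel=2)
        p = np.clip(p, _P_FLOOR, _P_CEIL)
    z = -ndtri(p)  # = Phi^-1(1 - p), stable for very small p
    return int(p.size), float(z.sum() / np.sqrt(p.size))


def genes_in_windows(
    genewise: GeneWisePvalues, window_bp: int = 1_000_000
) -> set[str]:
    """Genes whose body overlaps +/- window_bp around any lead SNP."""
    excluded: set[str] = set()
    for gene, (chrom, start, end) in genewise.coordinates.items():
        for snp_chrom, pos in genewise.lead_snps:
            if chrom == snp_chrom and start <= pos + window_bp and end >= pos - window_bp:
                excluded.add(gene)
                break
    return excluded


def permutation_test(
    network: nx.Graph | "object",
    linking_nodes: Iterable[str],
    genewise: GeneWisePvalues,
    interactome: Interactome,
    n_perm: int = 1000,
    window_bp: int = 1_000_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Degree-matched node-permutation test of linking-node enrichment.

    Each permutation draws one full replacement set for the linking
    nodes (jointly, not per node), matched on interactome degree within
    log2 bins, from genes with a gene-wise p-value that lie outside
    every lead-SNP exclusion window.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: unstable p-value", stacklevel=2)
    rng = np.random.default_rng(seed)

    graph = network.graph if isinstance(network.graph, nx.Graph) else network
    linking = sorted(linking_nodes)
    missing_in_net = [g for g in linking if g not in graph.nodes]
    if missing_in_net:
        raise ValueError(f"linking nodes not in network: {missing_in_net[:5]}")

    scored = [g for g in linking if g in genewise.pvalues]
    n_unscored = len(linking) - len(scored)
    if not scored:
        raise ValueError("no linking node carries a gene-wise p-value")
    k, zm_obs = stouffer_statistic([genewise.pvalues[g] for g in scored])

    excluded = genes_in_windows(genewise, window_bp)
    inter_index, _, _ = interactome._adjacency()
    pool = [
        g
        for g in sorted(genewise.pvalues)
        if g in inter_index and g not in excluded
    ]
    n_excluded_window = sum(1 for g in genewise.pvalues if g in inter_index) - len(pool)
    if not pool:
        raise ValueError("empty permutation pool after window exclusion")

    target_degrees = [interactome.degree(g) if g in inter_index else 0 for g in scored]
    zm_perm = _permuted_zms(pool, interactome, target_degrees, genewise, n_perm, rng)

    r = int(np.sum(zm_perm > zm_obs))
    return EnrichmentResult(
        trait=genewise.trait,
        k=k,
        zm_observed=zm_obs,
        permutation_zms=zm_perm,
        p_nominal=r / n_perm,
        p_addone=(r + 1) / (n_perm + 1),
        n_perm=n_perm,
        n_unscored=n_unscored,
        n_excluded_window=n_excluded_window,
    )


def _permuted_zms(
    pool: list[str],
    interactome: Interactome,
    target_degrees: list[int],
    genewise: GeneWisePvalues,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised permutation: per degree bin, draw without replacement
    for all permutations at once and accumulate Z sums."""
    p = np.clip(
        np.array([genewise.pvalues[g] for g in pool]), _P_FLOOR, _P_CEIL
    )
    z = -ndtri(p)  # = Phi^-1(1 - p), stable for very small p
    bins = np.array([_log_bin(interactome.degree(g)) for g in pool])

    needed: dict[int, int] = {}
    for d in target_degrees:
        b = _log_bin(d)
        needed[b] = needed.get(b, 0) + 1

    k = len(target_degrees)
    zsum = np.zeros(n_perm)
    for b in sorted(needed):
        count = needed[b]
        width = 0
        while True:
            mask = (bins >= b - width) & (bins <= b + width)
            idx = np.flatnonzero(mask)
            if idx.size >= count:
                break
            width += 1
            if width > 64:
                raise ValueError("cannot satisfy degree-matched permutation")
        if width > 0:
            warnings.warn(
                f"degree bin {b} widened by +/-{width} in permutation pool",
                stacklevel=3,
            )
        # rank of iid uniforms = random subset without replacement, per row
        u = rng.random((n_perm, idx.size))
        take = np.argpartition(u, count - 1, axis=1)[:, :count]
        zsum += z[idx[take]].sum(axis=1)
    return zsum / np.sqrt(k)


# ---------------------------------------------------------------------------
# Tissue-expression filtering and network comparison


@dataclass
class TissueExpression:
    tissue: str
    matrix: pd.DataFrame  # genes x samples, TPM

    def __post_init__(self):
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        if self.matrix.shape[1] < 1:
            raise ValueError("expression matrix needs at least one sample")

    def silent_genes(
        self, tpm_threshold: float = 0.1, sample_fraction: float = 0.5
    ) -> set[str]:
        low = (self.matrix < tpm_threshold).mean(axis=1)
        return set(low.index[low > sample_fraction])


def filter_by_expression(
    network: nx.Graph,
    expr: TissueExpression,
    tpm_threshold: float = 0.1,
    sample_fraction: float = 0.5,
) -> nx.Graph:
    """Remove nodes with TPM < threshold in strictly more than
    ``sample_fraction`` of the tissue's samples; genes absent from the
    expression matrix are retained (with a warning count)."""
    silent = expr.silent_genes(tpm_threshold, sample_fraction)
    uncovered = [n for n in network.nodes if n not in expr.matrix.index]
    if len(uncovered) == network.number_of_nodes():
        raise ValueError("expression matrix covers no network gene")
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} network gene(s) absent from {expr.tissue} "
            "expression; retained",
            stacklevel=2,
        )
    keep = [n for n in network.nodes if n not in silent]
    if not keep:
        raise ValueError("tissue filter removed all nodes")
    return network.subgraph(keep).copy()


def jaccard(network_a, network_b) -> float:
    """Jaccard index |A intersect B| / |A union B| over node sets."""
    a = set(network_a.nodes) if hasattr(network_a, "nodes") else set(network_a)
    b = set(network_b.nodes) if hasattr(network_b, "nodes") else set(network_b)
    union = a | b
    if not union:
        raise ValueError("both node sets are empty")
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Community decomposition


@dataclass
class Partition:
    communities: dict[str, int]  # node -> community id
    modularity: float


def detect_communities(network: nx.Graph, seed: int = 0) -> Partition:
    """Greedy modularity-maximising community decomposition.

    Community ids are assigned in decreasing community size, ties broken
    by the lexicographically smallest member, so the labelling is
    deterministic.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comms = nx.community.greedy_modularity_communities(network)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    mapping = {node: cid for cid, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(network, comms)
    return Partition(communities=mapping, modularity=float(q))
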