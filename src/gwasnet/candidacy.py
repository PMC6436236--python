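"""Positional candidacy scores (PCS) and seed-set selection.

The semantic score and the variant link score are each floored at zero
and rescaled to sum to one across the genes of a locus; the PCS of gene g
is their average renormalised over the locus,

    PCS_g = (s_g + v_g) / sum_i (s_i + v_i),

so PCS values form a simplex per locus. Seeds are the shortest
decreasing-PCS prefix whose cumulative PCS reaches the threshold
(default 0.70); their PCS values later serve as node prizes in the
network optimisation, which is why negativity is clipped here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass
class PcsRecord:
    gene: str
    locus_id: str
    s_g: float  # locus-normalised semantic score
    v_g: float  # locus-normalised variant link score
    pcs: float


@dataclass
class SeedSet:
    locus_id: str
    seeds: list[str]  # ordered by decreasing PCS
    cumulative_pcs: float


def _normalise(raw: np.ndarray) -> np.ndarray:
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total > 0:
        return clipped / total
    return clipped


def combine_scores(
    semantic: Mapping[str, float],
    variant_link: Mapping[str, float],
    loci: Mapping[str, list[str]],
) -> list[PcsRecord]:
    """Combine the two evidence channels into per-locus PCS records.

    Genes missing from either score map contribute 0 for that channel. A
    locus where both channels are entirely non-positive cannot be ranked
    and raises.
    """
    records: list[PcsRecord] = []
    for locus_id, genes in loci.items():
        if not genes:
            continue
        s_raw = np.array([semantic.get(g, 0.0) for g in genes], dtype=float)
        v_raw = np.array([variant_link.get(g, 0.0) for g in genes], dtype=float)
        s = _normalise(s_raw)
        v = _normalise(v_raw)
        total = (s + v).sum()
        if total <= 0:
            raise ValueError(f"unscorable locus {locus_id!r}: all scores zero")
        pcs = (s + v) / total
        records.extend(
            PcsRecord(gene=g, locus_id=locus_id, s_g=float(si), v_g=float(vi), pcs=float(p))
            for g, si, vi, p in zip(genes, s, v, pcs)
        )
    return records


def select_seeds(records: list[PcsRecord], threshold: float = 0.70) -> list[SeedSet]:
    """Minimal decreasing-PCS prefix per locus reaching the cumulative threshold.

    Ties in PCS are broken lexicographically by gene symbol so the seed
    set is deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    by_locus: dict[str, list[PcsRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus_id, []).append(r)
    out: list[SeedSet] = []
    for locus_id, recs in by_locus.items():
        ordered = sorted(recs, key=lambda r: (-r.pcs, r.gene))
        seeds: list[str] = []
        cum = 0.0
        for r in ordered:
            seeds.append(r.gene)
            cum += r.pcs
            if cum >= threshold - 1e-12:
                break
        out.append(SeedSet(locus_id=locus_id, seeds=seeds, cumulative_pcs=cum))
    return out


def seed_prizes(records: list[PcsRecord], seed_sets: list[SeedSet]) -> dict[str, float]:
    """Map each selected seed gene to its PCS (its prize in the network step)."""
    pcs_by_gene = {(r.locus_id, r.gene): r.pcs for r in records}
    prizes: dict[str, float] = {}
    for ss in seed_sets:
        for g in ss.seeds:
            prizes[g] = max(prizes.get(g, 0.0), pcs_by_gene[(ss.locus_id, g)])
    return prizes
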