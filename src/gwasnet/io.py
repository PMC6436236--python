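"""Readers and writers for the pipeline's plain-text file formats.

Internal coordinates are 1-based inclusive; BED input (0-based,
half-open) is converted at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .candidacy import PcsRecord, SeedSet
from .enrichment import EnrichmentResult, GeneWisePvalues, TissueExpression
from .variant_link import EqtlRecord, GeneAnnotation, Variant


# ---------------------------------------------------------------------------
# GWAS variants


def read_gwas_variants(path) -> list[Variant]:
    """TSV with columns SNP, CHR, POS, P, MAF, INFO (P -> -log10 internally)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = {"SNP", "CHR", "POS", "P", "MAF", "INFO"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        Variant(
            id=str(r.SNP),
            chromosome=str(r.CHR),
            position=int(r.POS),
            assoc_neglog10p=float(-np.log10(r.P)),
            maf=float(r.MAF),
            info=float(r.INFO),
        )
        for r in df.itertuples()
    ]


def write_gwas_variants(path, variants: list[Variant]) -> None:
    pd.DataFrame(
        {
            "SNP": [v.id for v in variants],
            "CHR": [v.chromosome for v in variants],
            "POS": [v.position for v in variants],
            "P": [10.0 ** -v.assoc_neglog10p for v in variants],
            "MAF": [v.maf for v in variants],
            "INFO": [v.info for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations (BED 0-based half-open on disk)


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """BED (chrom, start, end, name=gene) -> gene -> 1-based inclusive intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs 4 columns")
            start, end, gene = int(parts[1]), int(parts[2]), parts[3]
            out.setdefault(gene, []).append((start + 1, end))
    return out


def write_bed_intervals(path, intervals: dict[str, list[tuple[int, int]]],
                        chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for gene in sorted(intervals):
            for lo, hi in intervals[gene]:
                fh.write(f"{chrom}\t{lo - 1}\t{hi}\t{gene}\n")


def read_tss_table(path) -> dict[str, tuple[int, str]]:
    """TSV gene, tss, strand -> gene -> (tss, strand)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.gene): (int(r.tss), str(getattr(r, "strand", "+")))
        for r in df.itertuples()
    }


def write_tss_table(path, annotations: list[GeneAnnotation]) -> None:
    pd.DataFrame(
        {
            "gene": [a.gene for a in annotations],
            "tss": [a.tss for a in annotations],
            "strand": [a.strand for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def build_annotations(
    tss: dict[str, tuple[int, str]],
    exons: dict[str, list[tuple[int, int]]],
    distal: dict[str, list[tuple[int, int]]],
) -> list[GeneAnnotation]:
    """Assemble GeneAnnotation records; promoters derive from TSS/strand."""
    anns = []
    for gene in sorted(tss):
        t, strand = tss[gene]
        anns.append(
            GeneAnnotation(
                gene=gene,
                tss=t,
                strand=strand,
                exons=exons.get(gene, []),
                distal_elements=distal.get(gene, []),
            )
        )
    return anns


# ---------------------------------------------------------------------------
# eQTL records


def read_eqtls(path) -> list[EqtlRecord]:
    """TSV gene, variant, tissue, P."""
    df = pd.read_csv(path, sep="\t")
    return [
        EqtlRecord(
            gene=str(r.gene),
            variant_id=str(r.variant),
            tissue=str(r.tissue),
            neglog10p=float(-np.log10(r.P)),
        )
        for r in df.itertuples()
    ]


def write_eqtls(path, eqtls: list[EqtlRecord]) -> None:
    pd.DataFrame(
        {
            "gene": [e.gene for e in eqtls],
            "variant": [e.variant_id for e in eqtls],
            "tissue": [e.tissue for e in eqtls],
            "P": [10.0 ** -e.neglog10p for e in eqtls],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Corpus / query


def read_corpus(path) -> dict[str, list[str]]:
    """TSV gene<TAB>pipe-separated terms, or JSON {gene: [terms]}."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return {str(g): [str(t) for t in terms] for g, terms in data.items()}
    corpus: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, terms = line.partition("\t")
            corpus[gene] = [t for t in terms.split("|") if t]
    return corpus


def write_corpus(path, corpus: dict[str, list[str]]) -> None:
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(corpus, fh, indent=1)
        return
    with open(path, "w") as fh:
        for gene in sorted(corpus):
            fh.write(f"{gene}\t{'|'.join(corpus[gene])}\n")


def read_query_terms(path) -> list[str]:
    """Plain-text query: one term (possibly multi-word) per line."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_query_terms(path, terms: list[str]) -> None:
    Path(path).write_text("\n".join(terms) + "\n")


# ---------------------------------------------------------------------------
# PCS / seed tables


def write_pcs_table(path, records: list[PcsRecord], seed_sets: list[SeedSet]) -> None:
    """TSV locus_id, gene, s_g, v_g, pcs, is_seed."""
    seeded = {(ss.locus_id, g) for ss in seed_sets for g in ss.seeds}
    pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in records],
            "gene": [r.gene for r in records],
            "s_g": [r.s_g for r in records],
            "v_g": [r.v_g for r in records],
            "pcs": [r.pcs for r in records],
            "is_seed": [(r.locus_id, r.gene) in seeded for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pcs_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Interactome / networks


def write_edge_list(path, edges: list[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b, c in edges:
            fh.write(f"{a}\t{b}\t{c:.6g}\n")


def write_network(
    prefix, graph: nx.Graph, pcs: dict[str, float] | None = None,
    specificity: dict[str, float] | None = None,
) -> None:
    """GraphML plus TSV node table (node, label, pcs, specificity) and edges."""
    prefix = Path(prefix)
    nx.write_graphml(graph, str(prefix) + ".graphml")
    pcs = pcs or {}
    specificity = specificity or {}
    nodes = sorted(graph.nodes)
    pd.DataFrame(
        {
            "node": nodes,
            "label": [graph.nodes[n].get("label", "") for n in nodes],
            "pcs": [pcs.get(n, 0.0) for n in nodes],
            "specificity": [specificity.get(n, float("nan")) for n in nodes],
        }
    ).to_csv(str(prefix) + ".nodes.tsv", sep="\t", index=False)
    with open(str(prefix) + ".edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b, d in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d.get('confidence', float('nan')):.6g}\n")


# ---------------------------------------------------------------------------
# Gene-wise p-values / lead SNPs / expression


def read_genewise_pvalues(path, trait: str, lead_snp_path=None) -> GeneWisePvalues:
    """TSV gene, chrom, start, end, p (+ optional lead-SNP TSV trait, chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pvals = {str(r.gene): float(r.p) for r in df.itertuples()}
    coords = {
        str(r.gene): (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
    }
    leads: list[tuple[str, int]] = []
    if lead_snp_path is not None:
        ldf = pd.read_csv(lead_snp_path, sep="\t", dtype={"chrom": str})
        leads = [
            (str(r.chrom), int(r.pos))
            for r in ldf.itertuples()
            if str(r.trait) == trait
        ]
    return GeneWisePvalues(trait=trait, pvalues=pvals, coordinates=coords,
                           lead_snps=leads)


def write_genewise_pvalues(path, genewise: GeneWisePvalues) -> None:
    rows = []
    for gene, p in sorted(genewise.pvalues.items()):
        chrom, start, end = genewise.coordinates.get(gene, ("chr0", 0, 0))
        rows.append({"gene": gene, "chrom": chrom, "start": start, "end": end, "p": p})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lead_snps(path, trait: str, lead_snps: list[tuple[str, int]],
                    append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("trait\tchrom\tpos\n")
        for chrom, pos in lead_snps:
            fh.write(f"{trait}\t{chrom}\t{pos}\n")


def read_expression(path, tissue: str) -> TissueExpression:
    """TSV matrix: gene rows, sample columns."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return TissueExpression(tissue=tissue, matrix=matrix)


def write_expression(path, expr: TissueExpression) -> None:
    expr.matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reports


def write_enrichment_json(path, result: EnrichmentResult, seed: int) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "trait": result.trait,
                "k": result.k,
                "zm": result.zm_observed,
                "p_nominal": result.p_nominal,
                "p_addone": result.p_addone,
                "n_perm": result.n_perm,
                "n_unscored": result.n_unscored,
                "n_excluded_window": result.n_excluded_window,
                "seed": seed,
            },
            fh,
            indent=1,
        )


def write_communities(path, communities: dict[str, int], modularity: float) -> None:
    df = pd.DataFrame(
        sorted(communities.items()), columns=["node", "community"]
    )
    with open(path, "w") as fh:
        fh.write(f"# modularity\t{modularity:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)
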