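"""Synthetic pipeline inputs with planted, known structure.

Every stage of the pipeline can be exercised without external data:
loci with a planted effector gene whose eQTL signal drives the variant
association pattern; a scale-free interactome with a planted
densely-wired module; gene-wise association p-values with a planted
Z-shift in a chosen gene set; annotation corpora with a planted
query-vocabulary overlap; and tissue expression matrices with a planted
silent gene set. Each generator returns its ground truth alongside the
data, and is fully determined by the seed it is given.

The simulated genome is deliberately simple (one chromosome per locus,
evenly spaced genes) so that window arithmetic is auditable by eye; no
attempt is made to mimic linkage disequilibrium or real annotation-term
frequency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import norm

from .enrichment import GeneWisePvalues, TissueExpression
from .variant_link import EqtlRecord, GeneAnnotation, Variant

import pandas as pd


@dataclass
class FixtureConfig:
    """Knobs of the synthetic data generators (all seed-deterministic)."""

    seed: int = 0
    # locus / variant-link
    n_loci: int = 3
    genes_per_locus: int = 5
    variants_per_locus: int = 200
    effector_effect: float = 1.5
    eqtl_noise_sd: float = 0.3
    missing_eqtl_fraction: float = 0.0
    tissues_eqtl: tuple[str, ...] = ("islet",)
    # interactome
    interactome_nodes: int = 500
    attachment_edges: int = 3  # preferential-attachment edges per new node
    planted_module_size: int = 20
    module_extra_edge_p: float = 0.0  # chords beyond the closed backbone
    module_background_links: int = 1  # background edges kept per module node
    background_confidence: tuple[float, float] = (0.05, 0.75)
    module_confidence: tuple[float, float] = (0.88, 0.99)
    # gene-wise p-values
    n_traits: int = 2
    enrichment_shift: float = 1.5
    n_lead_snps: int = 5
    gene_spacing_bp: int = 400_000
    gene_length_bp: int = 10_000
    genes_per_chromosome: int = 50
    # corpus
    corpus_genes: int = 50
    n_relevant_genes: int = 10
    vocab_size: int = 400
    query_vocab_size: int = 40
    tokens_per_document: int = 30
    query_overlap_fraction: float = 0.5
    # expression
    tissues: tuple[str, ...] = ("islet", "liver")
    samples_per_tissue: int = 40
    silent_fraction: float = 0.3


# ---------------------------------------------------------------------------
# Locus fixtures


@dataclass
class LocusFixture:
    locus_id: str
    variants: list[Variant]
    annotations: list[GeneAnnotation]
    eqtls: list[EqtlRecord]
    effector: str  # planted truth


def simulate_locus(
    config: FixtureConfig,
    seed: int | None = None,
    locus_id: str = "locus1",
    gene_names: list[str] | None = None,
    effector: str | None = None,
) -> LocusFixture:
    """One GWAS locus where the planted effector's eQTL signal explains
    the variant association pattern.

    The effector gene's eQTL -log10 p column carries the signal: the
    variant association outcome is ``effector_effect`` times the
    standardised effector eQTL value plus Gaussian noise of sd
    ``eqtl_noise_sd`` (shifted to stay non-negative). Other genes'
    features are uninformative noise.
    """
    if config.genes_per_locus < 2:
        raise ValueError("need at least 2 genes per locus")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    window = 1_000_000
    chrom = locus_id

    if gene_names is None:
        genes = [f"{locus_id}_G{i}" for i in range(config.genes_per_locus)]
    else:
        if len(gene_names) != config.genes_per_locus:
            raise ValueError("gene_names length must equal genes_per_locus")
        genes = list(gene_names)
    spacing = window // (config.genes_per_locus + 1)
    annotations = []
    for i, gene in enumerate(genes):
        tss = spacing * (i + 1)
        exons = [(tss + off, tss + off + 199) for off in (0, 1000, 5000)]
        distal = [
            (int(d), int(d) + 499)
            for d in rng.integers(max(1, tss - 50_000), tss + 50_000, size=2)
        ]
        annotations.append(
            GeneAnnotation(gene=gene, tss=tss, strand="+", exons=exons,
                           distal_elements=distal)
        )
    if effector is None:
        effector = genes[int(rng.integers(config.genes_per_locus))]
    elif effector not in genes:
        raise ValueError("effector must be one of the locus genes")

    n = config.variants_per_locus
    positions = np.sort(rng.integers(1, window, size=n))
    n_missing = int(round(config.missing_eqtl_fraction * n))
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist()) if n_missing else set()

    # eQTL -log10 p per (gene, tissue, variant); effector column carries signal
    eqtls: list[EqtlRecord] = []
    effector_vals = np.abs(rng.normal(0.0, 1.5, size=n))
    signal = (effector_vals - effector_vals.mean()) / effector_vals.std()
    for vi in range(n):
        if vi in missing_idx:
            continue
        vid = f"{locus_id}_v{vi}"
        for gene in genes:
            for tissue in config.tissues_eqtl:
                if gene == effector and tissue == config.tissues_eqtl[0]:
                    val = effector_vals[vi]
                else:
                    val = float(np.abs(rng.normal(0.0, 0.5)))
                eqtls.append(
                    EqtlRecord(gene=gene, variant_id=vid, tissue=tissue,
                               neglog10p=val)
                )

    y = config.effector_effect * signal + rng.normal(0.0, config.eqtl_noise_sd, size=n)
    y = y - y.min()  # association -log10 p must be non-negative
    variants = [
        Variant(
            id=f"{locus_id}_v{vi}",
            chromosome=chrom,
            position=int(positions[vi]),
            assoc_neglog10p=float(y[vi]),
            maf=float(rng.uniform(0.01, 0.5)),
            info=float(rng.uniform(0.7, 1.0)),
        )
        for vi in range(n)
    ]
    return LocusFixture(
        locus_id=locus_id,
        variants=variants,
        annotations=annotations,
        eqtls=eqtls,
        effector=effector,
    )


# ---------------------------------------------------------------------------
# Interactome fixtures


@dataclass
class InteractomeFixture:
    edges: list[tuple[str, str, float]]
    module: list[str]  # planted truth
    hubs: list[str]  # highest-degree background nodes (decoy candidates)


def simulate_interactome(
    config: FixtureConfig, seed: int | None = None
) -> InteractomeFixture:
    """Scale-free background plus a planted pathway-like module.

    The background is a preferential-attachment graph (heavy-tailed
    degrees) with mid-range confidences, a tail of which falls below the
    high-confidence threshold and is thus removed on load. The module is
    a closed relay of high-confidence interactions (a cycle backbone
    over its members, optionally with extra chords): connectivity
    between module members is cheap but runs *through* other module
    members, which is what makes unseeded members recoverable as
    linking nodes. Relative to the sparse background the module is
    strongly over-connected.
    """
    if config.planted_module_size >= config.interactome_nodes:
        raise ValueError("planted module must be smaller than the interactome")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.interactome_nodes
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n, config.attachment_edges, seed=ba_seed)
    names = {i: f"G{i:04d}" for i in range(n)}

    degrees = dict(g.degree)
    order_by_degree = sorted(degrees, key=lambda v: (-degrees[v], v))
    n_top = max(1, n // 20)
    hubs = [names[v] for v in order_by_degree[:n_top]]
    non_hub = [v for v in order_by_degree[n_top:]]
    module_ids = sorted(
        rng.choice(non_hub, size=config.planted_module_size, replace=False).tolist()
    )
    module = [names[v] for v in module_ids]

    # module members interact mostly within the module (specialised
    # pathway): keep only a few background edges per member
    module_set = set(module_ids)
    kept_bg: dict[int, int] = {m: 0 for m in module_ids}
    bg_edges = []
    for a, b in sorted(g.edges):
        in_mod = [v for v in (a, b) if v in module_set]
        if in_mod:
            if any(kept_bg[v] >= config.module_background_links for v in in_mod):
                continue
            for v in in_mod:
                kept_bg[v] += 1
        bg_edges.append((a, b))

    lo, hi = config.background_confidence
    edges: dict[tuple[str, str], float] = {}
    for a, b in bg_edges:
        key = tuple(sorted((names[a], names[b])))
        edges[key] = float(rng.uniform(lo, hi))

    mlo, mhi = config.module_confidence
    perm = rng.permutation(module_ids)
    for i in range(len(perm)):
        a, b = int(perm[i]), int(perm[(i + 1) % len(perm)])
        key = tuple(sorted((names[a], names[b])))
        edges[key] = float(rng.uniform(mlo, mhi))
    if config.module_extra_edge_p > 0:
        for i, a in enumerate(module_ids):
            for b in module_ids[i + 1:]:
                key = tuple(sorted((names[a], names[b])))
                if key not in edges and rng.random() < config.module_extra_edge_p:
                    edges[key] = float(rng.uniform(mlo, mhi))

    edge_list = [(a, b, c) for (a, b), c in sorted(edges.items())]
    return InteractomeFixture(edges=edge_list, module=module, hubs=hubs)


# ---------------------------------------------------------------------------
# Gene-wise p-value fixtures


def simulate_genewise_pvalues(
    nodes: list[str],
    enriched: set[str] | list[str],
    shift: float,
    seed: int = 0,
    config: FixtureConfig | None = None,
    trait: str = "trait1",
) -> GeneWisePvalues:
    """Gene-wise p-values with a planted Z-shift in ``enriched``.

    Non-enriched genes: Z ~ N(0, 1); enriched genes: Z ~ N(shift, 1);
    p = 1 - Phi(Z). Genes are laid out on a synthetic genome
    (``genes_per_chromosome`` per chromosome, evenly spaced) and
    ``n_lead_snps`` lead SNPs are placed at the midpoints of randomly
    chosen gene bodies, so those genes fall inside exclusion windows.
    """
    config = config or FixtureConfig()
    enriched = set(enriched)
    if not enriched <= set(nodes):
        raise ValueError("enriched genes must be a subset of nodes")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=len(nodes))
    for i, gene in enumerate(nodes):
        if gene in enriched:
            z[i] += shift
    p = 1.0 - norm.cdf(z)

    coords: dict[str, tuple[str, int, int]] = {}
    for i, gene in enumerate(nodes):
        chrom = f"chr{i // config.genes_per_chromosome + 1}"
        start = (i % config.genes_per_chromosome) * config.gene_spacing_bp + 1
        coords[gene] = (chrom, start, start + config.gene_length_bp - 1)

    anchor_genes = rng.choice(len(nodes), size=min(config.n_lead_snps, len(nodes)),
                              replace=False)
    lead_snps = []
    for gi in sorted(anchor_genes.tolist()):
        chrom, start, end = coords[nodes[gi]]
        lead_snps.append((chrom, (start + end) // 2))

    return GeneWisePvalues(
        trait=trait,
        pvalues={g: float(pv) for g, pv in zip(nodes, p)},
        coordinates=coords,
        lead_snps=lead_snps,
    )


# ---------------------------------------------------------------------------
# Corpus fixtures


@dataclass
class CorpusFixture:
    corpus: dict[str, list[str]]  # gene -> raw term strings
    query_terms: list[str]
    relevant: list[str]  # planted truth


def simulate_corpus(
    config: FixtureConfig,
    seed: int | None = None,
    genes: list[str] | None = None,
    relevant: list[str] | None = None,
) -> CorpusFixture:
    """Annotation corpus where planted-relevant genes draw a fraction of
    their tokens from the query vocabulary."""
    if not 0 <= config.query_overlap_fraction <= 1:
        raise ValueError("query_overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    background = [f"process{i:03d}" for i in range(config.vocab_size)]
    query_vocab = [f"glycemic{i:02d}" for i in range(config.query_vocab_size)]

    if genes is None:
        genes = [f"CG{i:03d}" for i in range(config.corpus_genes)]
    if relevant is None:
        relevant = sorted(
            rng.choice(genes, size=config.n_relevant_genes, replace=False).tolist()
        )
    elif not set(relevant) <= set(genes):
        raise ValueError("relevant genes must be a subset of the corpus genes")
    relevant = sorted(relevant)
    relevant_set = set(relevant)

    corpus: dict[str, list[str]] = {}
    for gene in genes:
        terms = []
        for _ in range(config.tokens_per_document):
            if gene in relevant_set and rng.random() < config.query_overlap_fraction:
                terms.append(query_vocab[int(rng.integers(len(query_vocab)))])
            else:
                terms.append(background[int(rng.integers(len(background)))])
        corpus[gene] = terms
    return CorpusFixture(corpus=corpus, query_terms=list(query_vocab), relevant=relevant)


# ---------------------------------------------------------------------------
# Expression fixtures


@dataclass
class ExpressionFixture:
    expression: dict[str, TissueExpression]  # tissue -> matrix
    silent: dict[str, set[str]]  # tissue -> planted silent genes


def simulate_expression(
    genes: list[str], config: FixtureConfig, seed: int | None = None
) -> ExpressionFixture:
    """Per-tissue TPM matrices with a planted silent gene set.

    Silent genes draw TPM from an exponential with mean well below the
    0.1 threshold; expressed genes from a log-normal well above it. The
    generated matrix is post-corrected so that the planted labels match
    the TPM rule exactly (silent iff TPM < 0.1 in > 50% of samples).
    """
    if not 0 <= config.silent_fraction < 1:
        raise ValueError("silent_fraction must lie in [0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_silent = int(round(config.silent_fraction * len(genes)))
    out_expr: dict[str, TissueExpression] = {}
    out_silent: dict[str, set[str]] = {}
    n_samp = config.samples_per_tissue
    majority = n_samp // 2 + 1  # smallest count that is > 50%
    for tissue in config.tissues:
        silent = set(
            rng.choice(genes, size=n_silent, replace=False).tolist()
        ) if n_silent else set()
        rows = []
        for gene in genes:
            if gene in silent:
                tpm = rng.exponential(0.03, size=n_samp)
                if (tpm < 0.1).sum() < majority:  # enforce the planted label
                    tpm[:majority] = rng.uniform(0.0, 0.09, size=majority)
            else:
                tpm = rng.lognormal(1.0, 1.0, size=n_samp)
                low = tpm < 0.1
                if low.sum() * 2 > n_samp:
                    tpm[low] = rng.uniform(0.2, 1.0, size=int(low.sum()))
            rows.append(tpm)
        matrix = pd.DataFrame(
            np.vstack(rows), index=genes,
            columns=[f"{tissue}_s{j}" for j in range(n_samp)],
        )
        out_expr[tissue] = TissueExpression(tissue=tissue, matrix=matrix)
        out_silent[tissue] = silent
    return ExpressionFixture(expression=out_expr, silent=out_silent)


# ---------------------------------------------------------------------------
# Full input bundle for end-to-end runs


def write_fixture_bundle(outdir, config: FixtureConfig) -> dict:
    """Write a complete, mutually consistent input bundle to ``outdir``.

    Locus genes are drawn from the interactome's node names, with each
    locus's planted effector placed inside the planted module, so the
    scoring, network and enrichment stages connect end to end. Returns
    the truth dictionary (also written as truth.json) and writes a ready
    pipeline config.yaml.
    """
    import json
    from pathlib import Path

    from . import io as gio
    from .config import (
        ApcstConfig, EnrichmentOptions, LocusInputs, PipelineConfig,
        SemanticOptions, TissueFilterOptions, TissueInputs, TraitInputs,
        derive_seed,
    )
    from .variant_link import RegressionConfig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(derive_seed(config.seed, "bundle"))

    inter = simulate_interactome(config, seed=derive_seed(config.seed, "interactome"))
    gio.write_edge_list(outdir / "interactome.tsv", inter.edges)
    all_nodes = sorted({n for a, b, _ in inter.edges for n in (a, b)})
    non_module = [n for n in all_nodes if n not in set(inter.module)]

    if config.n_loci > len(inter.module):
        raise ValueError("need at least one module gene per locus")
    effectors = rng.choice(inter.module, size=config.n_loci, replace=False).tolist()
    available = list(non_module)
    rng.shuffle(available)

    loci_inputs = []
    loci_genes: dict[str, list[str]] = {}
    truth_effectors: dict[str, str] = {}
    for li in range(config.n_loci):
        locus_id = f"locus{li + 1}"
        others = [available.pop() for _ in range(config.genes_per_locus - 1)]
        genes = sorted(others + [effectors[li]])
        fx = simulate_locus(
            config,
            seed=derive_seed(config.seed, f"locus:{locus_id}"),
            locus_id=locus_id,
            gene_names=genes,
            effector=effectors[li],
        )
        loci_genes[locus_id] = genes
        truth_effectors[locus_id] = fx.effector
        gio.write_gwas_variants(outdir / f"{locus_id}.gwas.tsv", fx.variants)
        gio.write_bed_intervals(
            outdir / f"{locus_id}.exons.bed",
            {a.gene: a.exons for a in fx.annotations}, chrom=locus_id,
        )
        gio.write_bed_intervals(
            outdir / f"{locus_id}.distal.bed",
            {a.gene: a.distal_elements for a in fx.annotations}, chrom=locus_id,
        )
        gio.write_tss_table(outdir / f"{locus_id}.tss.tsv", fx.annotations)
        gio.write_eqtls(outdir / f"{locus_id}.eqtl.tsv", fx.eqtls)
        loci_inputs.append(
            LocusInputs(
                locus_id=locus_id,
                gwas=str(outdir / f"{locus_id}.gwas.tsv"),
                exons_bed=str(outdir / f"{locus_id}.exons.bed"),
                distal_bed=str(outdir / f"{locus_id}.distal.bed"),
                tss=str(outdir / f"{locus_id}.tss.tsv"),
                eqtl=str(outdir / f"{locus_id}.eqtl.tsv"),
            )
        )

    locus_gene_list = sorted({g for gs in loci_genes.values() for g in gs})
    corpus_fx = simulate_corpus(
        config,
        seed=derive_seed(config.seed, "corpus"),
        genes=locus_gene_list,
        relevant=sorted(truth_effectors.values()),
    )
    gio.write_corpus(outdir / "corpus.tsv", corpus_fx.corpus)
    gio.write_query_terms(outdir / "query.txt", corpus_fx.query_terms)

    traits = []
    lead_path = outdir / "lead_snps.tsv"
    for ti in range(config.n_traits):
        trait = f"trait{ti + 1}"
        gw = simulate_genewise_pvalues(
            all_nodes,
            enriched=set(inter.module),
            shift=config.enrichment_shift,
            seed=derive_seed(config.seed, f"genewise:{trait}"),
            config=config,
            trait=trait,
        )
        gio.write_genewise_pvalues(outdir / f"{trait}.genewise.tsv", gw)
        gio.write_lead_snps(lead_path, trait, gw.lead_snps, append=ti > 0)
        traits.append(TraitInputs(trait=trait, genewise=str(outdir / f"{trait}.genewise.tsv")))

    expr_fx = simulate_expression(
        all_nodes, config, seed=derive_seed(config.seed, "expression")
    )
    tissues = []
    for tissue, expr in expr_fx.expression.items():
        gio.write_expression(outdir / f"{tissue}.expression.tsv", expr)
        tissues.append(TissueInputs(tissue=tissue, expression=str(outdir / f"{tissue}.expression.tsv")))

    truth = {
        "effectors": truth_effectors,
        "module": inter.module,
        "hubs": inter.hubs,
        "relevant_genes": corpus_fx.relevant,
        "silent": {t: sorted(s) for t, s in expr_fx.silent.items()},
        "loci_genes": loci_genes,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    pipeline_config = PipelineConfig(
        loci=loci_inputs,
        corpus=str(outdir / "corpus.tsv"),
        query=str(outdir / "query.txt"),
        interactome=str(outdir / "interactome.tsv"),
        traits=traits,
        lead_snps=str(lead_path),
        tissues=tissues,
        regression=RegressionConfig(seed=derive_seed(config.seed, "regression")),
        semantic=SemanticOptions(),
        apcst=ApcstConfig(seed=derive_seed(config.seed, "apcst")),
        enrichment=EnrichmentOptions(),
        tissue_filter=TissueFilterOptions(),
        seed=config.seed,
    )
    pipeline_config.to_yaml(outdir / "config.yaml")
    return truth
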