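"""End-to-end orchestration of the scoring -> network -> enrichment run.

Stages (in order): variant link scoring, semantic scoring, candidacy
(PCS + seed selection), APCST ensemble, specificity, enrichment (per
trait) with tissue filtering, and community decomposition. Every output
is written under the run directory together with a manifest recording
stage checksums and the seeds used, so reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import io as gio
from .apcst import (
    ApcstConfig, PrizeMap, assess_specificity, load_interactome,
    run_rooted_ensemble,
)
from .candidacy import combine_scores, seed_prizes, select_seeds
from .config import PipelineConfig, derive_seed
from .enrichment import (
    detect_communities, filter_by_expression, jaccard, permutation_test,
)
from .semantic import semantic_scores_from_corpus, load_stopwords
from .variant_link import variant_link_scores

log = logging.getLogger("gwasnet")

STAGES = (
    "variant_link",
    "semantic",
    "candidacy",
    "network",
    "specificity",
    "enrichment",
    "communities",
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.used.yaml")
    manifest: dict = {"stages": {}, "seed": config.seed}

    def record(stage: str, outputs: list[Path]):
        manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in outputs},
            "seed": derive_seed(config.seed, stage),
        }
        log.info("stage %s complete (%d output file(s))", stage, len(outputs))

    # --- variant link scoring -------------------------------------------
    stage = "variant_link"
    try:
        import dataclasses
        reg = dataclasses.replace(
            config.regression, seed=derive_seed(config.seed, stage)
        )
        vls: dict[str, float] = {}
        loci_genes: dict[str, list[str]] = {}
        for locus in config.loci:
            variants = gio.read_gwas_variants(locus.gwas)
            tss = gio.read_tss_table(locus.tss)
            anns = gio.build_annotations(
                tss,
                gio.read_bed_intervals(locus.exons_bed),
                gio.read_bed_intervals(locus.distal_bed),
            )
            eqtls = gio.read_eqtls(locus.eqtl)
            scores = variant_link_scores(
                variants, anns, eqtls, config=reg,
                exon_scale=config.exon_scale, locus_id=locus.locus_id,
            )
            loci_genes[locus.locus_id] = sorted(scores)
            vls.update(scores)
        record(stage, [])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- semantic scoring ------------------------------------------------
    stage = "semantic"
    try:
        corpus = gio.read_corpus(config.corpus)
        query = gio.read_query_terms(config.query)
        stopwords = (
            load_stopwords(config.semantic.stopwords)
            if config.semantic.stopwords
            else None
        )
        sem = semantic_scores_from_corpus(
            corpus, query, stopwords=stopwords,
            share=config.semantic.share, space=config.semantic.space,
        )
        record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- candidacy --------------------------------------------------------
    stage = "candidacy"
    try:
        records = combine_scores(sem, vls, loci_genes)
        seed_sets = select_seeds(records, threshold=config.candidacy_threshold)
        pcs_path = outdir / "pcs.tsv"
        gio.write_pcs_table(pcs_path, records, seed_sets)
        prizes_map = seed_prizes(records, seed_sets)
        record(stage, [pcs_path])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- APCST ensemble ---------------------------------------------------
    stage = "network"
    try:
        import dataclasses
        interactome = load_interactome(
            config.interactome,
            confidence_threshold=config.apcst.confidence_threshold,
        )
        apcst_cfg = dataclasses.replace(
            config.apcst, seed=derive_seed(config.seed, stage)
        )
        prizes = PrizeMap(prizes=prizes_map)
        ensemble = run_rooted_ensemble(interactome, prizes, apcst_cfg)
        record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- specificity ------------------------------------------------------
    stage = "specificity"
    try:
        spec_cfg = dataclasses.replace(
            apcst_cfg, seed=derive_seed(config.seed, stage)
        )
        report = assess_specificity(
            ensemble, interactome, prizes, spec_cfg,
            n_random=config.n_random_specificity,
        )
        prefix = outdir / "ensemble"
        gio.write_network(
            prefix, ensemble.graph, pcs=prizes_map,
            specificity=report.specificity,
        )
        outputs = [Path(str(prefix) + s) for s in (".graphml", ".nodes.tsv", ".edges.tsv")]
        record(stage, outputs)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- enrichment (per trait, with tissue-filtered variants) -----------
    stage = "enrichment"
    try:
        linking = ensemble.linking_nodes
        expr_by_tissue = {
            t.tissue: gio.read_expression(t.expression, t.tissue)
            for t in config.tissues
        }
        outputs = []
        for trait_cfg in config.traits:
            gw = gio.read_genewise_pvalues(
                trait_cfg.genewise, trait_cfg.trait, lead_snp_path=config.lead_snps
            )
            eseed = derive_seed(config.seed, f"{stage}:{trait_cfg.trait}")
            result = permutation_test(
                ensemble.graph, linking, gw, interactome,
                n_perm=config.enrichment.n_perm,
                window_bp=config.enrichment.window_bp,
                seed=eseed,
            )
            path = outdir / f"enrichment.{trait_cfg.trait}.json"
            gio.write_enrichment_json(path, result, seed=eseed)
            outputs.append(path)
        tissue_nodes = {}
        for tissue, expr in expr_by_tissue.items():
            filtered = filter_by_expression(
                ensemble.graph, expr,
                tpm_threshold=config.tissue_filter.tpm_threshold,
                sample_fraction=config.tissue_filter.sample_fraction,
            )
            tissue_nodes[tissue] = set(filtered.nodes)
            prefix = outdir / f"ensemble.{tissue}"
            gio.write_network(prefix, filtered, pcs=prizes_map)
            outputs.append(Path(str(prefix) + ".nodes.tsv"))
        if len(tissue_nodes) >= 2:
            names = sorted(tissue_nodes)
            jmat = {
                a: {b: jaccard(tissue_nodes[a], tissue_nodes[b]) for b in names}
                for a in names
            }
            jpath = outdir / "tissue_jaccard.json"
            jpath.write_text(json.dumps(jmat, indent=1))
            outputs.append(jpath)
        record(stage, outputs)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- communities ------------------------------------------------------
    stage = "communities"
    try:
        partition = detect_communities(
            ensemble.graph, seed=derive_seed(config.seed, stage)
        )
        cpath = outdir / "communities.tsv"
        gio.write_communities(cpath, partition.communities, partition.modularity)
        record(stage, [cpath])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest["n_stages"] = len(manifest["stages"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
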