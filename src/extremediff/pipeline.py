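"""End-to-end orchestration: filter -> contrast -> annotate -> enrich -> prioritize."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

from pyfaidx import Fasta

from extremediff.annotator import (
    GeneIndex,
    annotate_sites,
    attach_to_genes,
    load_gene_models,
    summarize_categories,
    write_annotation_tsv,
)
from extremediff.config import PipelineConfig
from extremediff.enrichment import (
    read_gmt,
    run_ora,
    select_functional_genes,
    write_enrichment_tsv,
    write_selected_genes_tsv,
)
from extremediff.family_contrast import FamilyDesign, common_differential, write_differential_tsv
from extremediff.prioritizer import (
    GeneticMap,
    read_qtl_csv,
    select_candidates,
    write_candidates_tsv,
)
from extremediff.variant_filter import build_matrix, read_design

log = logging.getLogger(__name__)


def run_pipeline(
    inputs: Mapping,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the whole analysis and write every intermediate table.

    inputs must provide: "vcfs" (mapping sample -> VCF path, or list of
    single-sample VCFs), "design", "gff", "fasta", "gmt", "map", "qtl".
    Returns a report dict with per-stage record counts and the final
    candidates; outputs are byte-identical across reruns on identical
    inputs.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    design_rows = _stage("design", read_design, inputs["design"])
    design = FamilyDesign.from_rows(design_rows)

    matrix = _stage("filter", build_matrix, inputs["vcfs"], design_rows, cfg)
    matrix.to_tsv(out_dir / "matrix.tsv")
    log.info("filter: %d sites x %d samples", len(matrix.sites), len(matrix.samples))

    diffs = _stage("contrast", common_differential, matrix, design)
    write_differential_tsv(diffs, out_dir / "differential.tsv")
    log.info("contrast: %d common differential SNVs", len(diffs))

    genes = _stage("annotate", load_gene_models, inputs["gff"])
    index = GeneIndex(genes)
    reference = Fasta(str(inputs["fasta"]))
    diff_sites = [(d.chromosome, d.position, d.ref, d.alt) for d in diffs]
    annotations = _stage("annotate", annotate_sites, diff_sites, index, reference, cfg)
    write_annotation_tsv(annotations, out_dir / "annotations.tsv")
    if annotations:
        summarize_categories(annotations).to_tsv(out_dir / "summary_differential.tsv")

    attachments, retained = _stage("annotate", attach_to_genes, diff_sites, annotations, index, cfg)
    attached_sites = {site for site, *_rest in attachments}
    if attached_sites:
        near_anns = [a for a in annotations if a.site in attached_sites]
        summarize_categories(near_anns).to_tsv(out_dir / "summary_near_gene.tsv")
    query = sorted({gene_id for _s, _a, gene_id, _d in attachments})
    background = sorted(g.gene_id for g in genes)
    log.info("annotate: %d/%d SNVs within %d bp of a gene; %d query genes",
             retained, len(diffs), cfg.gene_window_bp, len(query))

    collections = _stage("enrich", read_gmt, inputs["gmt"])
    results = _stage("enrich", run_ora, query, collections, background, cfg) if query else []
    write_enrichment_tsv(results, out_dir / "enrichment.tsv")
    functional = _stage("enrich", select_functional_genes, results, collections, query, cfg)
    write_selected_genes_tsv(functional, out_dir / "functional_genes.tsv")
    log.info("enrich: %d sets tested, %d significant, %d functional genes",
             len(results), sum(r.significant for r in results), len(functional))

    genetic_map = _stage("prioritize", GeneticMap.from_csv, inputs["map"])
    qtls = _stage("prioritize", read_qtl_csv, inputs["qtl"])
    diffs_by_site = {(d.chromosome, d.position, d.ref, d.alt): d for d in diffs}
    candidates = _stage(
        "prioritize", select_candidates, functional, attachments, diffs_by_site,
        index, genetic_map, qtls, cfg,
    )
    write_candidates_tsv(candidates, out_dir / "candidates.tsv")
    log.info("prioritize: %d candidate genes", len(candidates))

    report = {
        "n_sites": len(matrix.sites),
        "n_samples": len(matrix.samples),
        "n_differential_raw": len(diffs),
        "n_differential_annotated": len(annotations),
        "n_near_gene_snvs": retained,
        "n_query_genes": len(query),
        "n_sets_tested": len(results),
        "n_significant_sets": sum(r.significant for r in results),
        "n_functional_genes": len(functional),
        "n_candidates": len(candidates),
        "candidate_genes": [c.gene_id for c in candidates],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["candidates"] = candidates
    return report
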