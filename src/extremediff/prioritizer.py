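"""Genetic-map interpolation, QTL-peak proximity and the candidate report.

Genes are mapped from physical (bp) to genetic (cM) coordinates by
piecewise-linear interpolation between map anchors, and a gene survives
only if its unrounded distance to the nearest milk protein/fat QTL peak
is below 1 cM and it carries a regulatory or exonic common differential
SNV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from extremediff._util import chrom_sort_key, round_half_up
from extremediff.annotator import REGULATORY_OR_EXONIC, GeneIndex
from extremediff.config import PipelineConfig


class GeneticMap:
    """Per-chromosome (bp, cM) anchors, strictly increasing on both axes."""

    def __init__(self, anchors: dict):
        self.anchors = {}
        for chrom, pairs in anchors.items():
            pairs = sorted(pairs)
            bp = np.array([p[0] for p in pairs], dtype=float)
            cm = np.array([p[1] for p in pairs], dtype=float)
            if len(bp) < 2:
                raise ValueError(f"chromosome {chrom}: a map needs >= 2 anchors")
            if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
                raise ValueError(f"chromosome {chrom}: anchors must be strictly increasing")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneticMap":
        anchors: dict = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                anchors.setdefault(row["chromosome"], []).append((int(row["bp"]), float(row["cM"])))
        return cls(anchors)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["chromosome", "bp", "cM"])
            for chrom in sorted(self.anchors, key=chrom_sort_key):
                bp, cm = self.anchors[chrom]
                for b, c in zip(bp, cm):
                    w.writerow([chrom, int(b), f"{c:.6g}"])


def interpolate_cM(genetic_map: GeneticMap, chromosome: str, bp: float) -> float:
    """Piecewise-linear bp -> cM; terminal-segment extrapolation beyond ends."""
    if chromosome not in genetic_map.anchors:
        raise ValueError(f"chromosome {chromosome!r} not in the genetic map")
    xs, ys = genetic_map.anchors[chromosome]
    if bp <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (bp - xs[0]))
    if bp >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (bp - xs[-1]))
    return float(np.interp(bp, xs, ys))


@dataclass(frozen=True)
class QTLRecord:
    chromosome: str
    trait: str  # PP | PY | FP | FY
    ci_start_cM: float
    ci_end_cM: float
    peaks_cM: tuple
    source: str

    def __post_init__(self) -> None:
        if self.ci_start_cM > self.ci_end_cM:
            raise ValueError("QTL confidence interval start exceeds end")
        if not self.peaks_cM:
            raise ValueError("QTL record needs at least one peak")


def read_qtl_csv(path: str | Path) -> list:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                QTLRecord(
                    chromosome=row["chromosome"],
                    trait=row["trait"],
                    ci_start_cM=float(row["ci_start_cM"]),
                    ci_end_cM=float(row["ci_end_cM"]),
                    peaks_cM=tuple(float(p) for p in row["peaks_cM"].split(";")),
                    source=row["source"],
                )
            )
    return records


def write_qtl_csv(records: Sequence[QTLRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["chromosome", "trait", "ci_start_cM", "ci_end_cM", "peaks_cM", "source"])
        for r in records:
            w.writerow(
                [r.chromosome, r.trait, f"{r.ci_start_cM:.6g}", f"{r.ci_end_cM:.6g}",
                 ";".join(f"{p:.6g}" for p in r.peaks_cM), r.source]
            )


def qtl_min_distance(
    gene_cM: float,
    records: Sequence[QTLRecord],
    chromosome: str,
    traits: frozenset | None = None,
) -> tuple:
    """Minimum |gene_cM - peak| over trait-filtered QTL peaks on the chromosome.

    Returns (distance, record, peak); (None, None, None) when no QTL
    survives the filter — callers exclude such genes. Selection uses the
    unrounded distance; display rounds half-up to 1 decimal.
    """
    best = (None, None, None)
    for rec in records:
        if rec.chromosome != chromosome:
            continue
        if traits is not None and rec.trait not in traits:
            continue
        for peak in rec.peaks_cM:
            d = abs(gene_cM - peak)
            if best[0] is None or d < best[0]:
                best = (d, rec, peak)
    return best


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    gene_cM: float
    supporting_snvs: tuple  # ((position, category, high_allele, low_allele), ...)
    admitted_by: tuple
    qtl_source: str
    qtl_trait: str
    qtl_peak_cM: float
    qtl_distance_cM: float  # unrounded

    @property
    def qtl_distance_display(self) -> float:
        return round_half_up(self.qtl_distance_cM, 1)


def gene_cm_position(gene, genetic_map: GeneticMap, config: PipelineConfig) -> float:
    bp = gene.start if config.gene_cm_from == "start" else (gene.start + gene.end) / 2.0
    return interpolate_cM(genetic_map, gene.chromosome, bp)


def select_candidates(
    functional_genes: dict,
    attachments: Sequence[tuple],
    diffs_by_site: dict,
    genes: GeneIndex,
    genetic_map: GeneticMap,
    qtls: Sequence[QTLRecord],
    config: PipelineConfig | None = None,
) -> list:
    """Final candidate-gene selection.

    A gene is retained iff (a) it is in the trait-relevant functional
    set, (b) its unrounded minimum QTL-peak distance for a milk
    protein/fat trait is below qtl_max_cM, and (c) at least one attached
    common differential SNV falls in an exonic, UTR or up/downstream
    category (intronic or intergenic support alone does not qualify).

    functional_genes: {gene: provenance list} from select_functional_genes.
    attachments: (site, annotation, gene_id, distance) tuples.
    diffs_by_site: {(chrom, pos, ref, alt): DifferentialSNV}.
    """
    cfg = config or PipelineConfig()
    gene_by_id = {g.gene_id: g for g in genes.genes}
    support: dict = {}
    for site, ann, gene_id, _dist in attachments:
        # support must come from the SNV's own assigned category/gene
        if ann.category in REGULATORY_OR_EXONIC and ann.gene_id == gene_id:
            support.setdefault(gene_id, []).append((site, ann))

    candidates = []
    for gene_id, provenance in functional_genes.items():
        if gene_id not in support:
            continue
        gene = gene_by_id[gene_id]
        cm = gene_cm_position(gene, genetic_map, cfg)
        dist, rec, peak = qtl_min_distance(cm, qtls, gene.chromosome, cfg.traits)
        if dist is None or dist >= cfg.qtl_max_cM:
            continue
        snvs = tuple(
            (site[1], ann.category, diffs_by_site[site].high_allele, diffs_by_site[site].low_allele)
            for site, ann in sorted(support[gene_id], key=lambda x: x[0][1])
        )
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                chromosome=gene.chromosome,
                start=gene.start,
                end=gene.end,
                gene_cM=cm,
                supporting_snvs=snvs,
                admitted_by=tuple(provenance),
                qtl_source=rec.source,
                qtl_trait=rec.trait,
                qtl_peak_cM=peak,
                qtl_distance_cM=dist,
            )
        )
    candidates.sort(key=lambda c: (chrom_sort_key(c.chromosome), c.start, c.gene_id))
    return candidates


def write_candidates_tsv(candidates: Sequence[CandidateGene], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "chromosome", "start", "end", "gene_cM",
             "snv_positions", "snv_categories", "high_alleles", "low_alleles",
             "qtl_source", "qtl_trait", "qtl_peak_cM", "qtl_distance_cM", "admitted_by"]
        )
        for c in candidates:
            w.writerow(
                [c.gene_id, c.chromosome, c.start, c.end, f"{c.gene_cM:.4f}",
                 ";".join(str(p) for p, *_x in c.supporting_snvs),
                 ";".join(cat for _p, cat, *_x in c.supporting_snvs),
                 ";".join(h for *_x, h, _l in c.supporting_snvs),
                 ";".join(l for *_x, l in c.supporting_snvs),
                 c.qtl_source, c.qtl_trait, f"{c.qtl_peak_cM:.4f}",
                 f"{c.qtl_distance_display:.1f}", ";".join(c.admitted_by)]
            )
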