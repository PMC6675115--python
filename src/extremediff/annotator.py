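"""Functional region annotation of SNVs against gene models.

Each site receives exactly one of nine categories — exonic, UTR5, UTR3,
intronic, ncRNA_exonic, ncRNA_intronic, upstream, downstream,
upstream;downstream (within 1 kb of a gene) or intergenic (farther) —
with a mutually exclusive precedence, and exonic sites get a coding
effect (synonymous / nonsynonymous / stopgain / stoploss / unknown) by
substituting the alt base into the spliced CDS and translating.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

from extremediff._util import chrom_sort_key, round_half_up
from extremediff.config import PipelineConfig

# precedence for sites matching multiple features (highest first)
CATEGORY_PRIORITY = ["exonic", "UTR5", "UTR3", "intronic", "ncRNA_exonic", "ncRNA_intronic"]

#: display order of the category vocabulary
CATEGORIES = [
    "intergenic",
    "upstream",
    "downstream",
    "upstream;downstream",
    "UTR3",
    "UTR5",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "intronic",
    "exonic",
]

EXONIC_EFFECTS = ["nonsynonymous", "synonymous", "stopgain", "stoploss", "unknown"]

#: categories treated as potentially regulatory/coding for candidate support
REGULATORY_OR_EXONIC = frozenset(
    {"exonic", "UTR5", "UTR3", "upstream", "downstream", "upstream;downstream"}
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple  # ((start, end), ...) 1-based inclusive, ascending
    cds: tuple  # ((start, end), ...) ascending; empty for ncRNA
    utr5: tuple
    utr3: tuple


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based inclusive span
    end: int
    biotype: str  # "coding" | "ncRNA"
    transcripts: tuple

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def boundary_distance(self, pos: int) -> int:
        """0 inside the span, else distance to the nearest span boundary."""
        if self.contains(pos):
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))

    def side(self, pos: int) -> str | None:
        """upstream/downstream classification of an external position."""
        if self.contains(pos):
            return None
        left = pos < self.start
        if self.strand == "+":
            return "upstream" if left else "downstream"
        return "downstream" if left else "upstream"


@dataclass(frozen=True)
class AnnotationRecord:
    site: tuple  # (chromosome, position, ref, alt)
    category: str
    exonic_effect: str  # not_applicable unless category == exonic
    gene_id: str | None
    distance_bp: int
    ref_mismatch: bool = False


def _in_any(pos: int, intervals: Sequence[tuple]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def load_gene_models(gff_path: str | Path) -> list:
    """Parse GFF3 gene/transcript/exon/CDS/UTR features into GeneModels."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        biotype = g.attributes.get("biotype", ["protein_coding"])[0]
        transcripts = []
        for t in db.children(g, level=1):
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(t, level=1):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            transcripts.append(
                Transcript(
                    transcript_id=t.id,
                    chromosome=g.seqid,
                    strand=g.strand,
                    exons=tuple(sorted(exons)),
                    cds=tuple(sorted(cds)),
                    utr5=tuple(sorted(utr5)),
                    utr3=tuple(sorted(utr3)),
                )
            )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                biotype="ncRNA" if biotype in ("ncRNA", "non_coding") else "coding",
                transcripts=tuple(transcripts),
            )
        )
    genes.sort(key=lambda g: (chrom_sort_key(g.chromosome), g.start, g.gene_id))
    return genes


class GeneIndex:
    """Interval-indexed gene models for containment and proximity queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.by_chrom: dict = {}
        self.trees: dict = {}
        for g in self.genes:
            self.by_chrom.setdefault(g.chromosome, []).append(g)
            self.trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, g)

    def containing(self, chrom: str, pos: int) -> list:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.gene_id)

    def within(self, chrom: str, pos: int, window: int) -> list:
        """Genes whose span boundary lies within `window` bp (incl. containing)."""
        return sorted(
            (g for g in self.by_chrom.get(chrom, []) if g.boundary_distance(pos) <= window),
            key=lambda g: (g.boundary_distance(pos), g.gene_id),
        )

    def nearest_distance(self, chrom: str, pos: int) -> int | None:
        genes = self.by_chrom.get(chrom)
        if not genes:
            return None
        return min(g.boundary_distance(pos) for g in genes)


def _internal_category(gene: GeneModel, pos: int) -> str:
    """Category of a position inside a gene span."""
    if gene.biotype == "ncRNA":
        for t in gene.transcripts:
            if _in_any(pos, t.exons):
                return "ncRNA_exonic"
        return "ncRNA_intronic"
    best = None
    for t in gene.transcripts:
        if _in_any(pos, t.cds):
            cat = "exonic"
        elif _in_any(pos, t.utr5):
            cat = "UTR5"
        elif _in_any(pos, t.utr3):
            cat = "UTR3"
        else:
            cat = "intronic"
        if best is None or CATEGORY_PRIORITY.index(cat) < CATEGORY_PRIORITY.index(best):
            best = cat
    return best or "intronic"


def coding_effect(site: tuple, transcript: Transcript, reference: Fasta) -> str:
    """Effect of substituting the alt base at an in-CDS site.

    The reference codon is read from the spliced CDS in transcript
    orientation (reverse-complemented on the minus strand), the alt base
    substituted, and both codons translated with the standard genetic
    code. A CDS length not divisible by 3, or a reference base that does
    not match the site's ref allele, yields "unknown".
    """
    chrom, pos, ref, alt = site
    if not _in_any(pos, transcript.cds):
        raise ValueError(f"site {chrom}:{pos} is not inside a CDS of {transcript.transcript_id}")
    spliced = ""
    offset = None
    for s, e in transcript.cds:
        if s <= pos <= e:
            offset = len(spliced) + (pos - s)
        spliced += str(reference[chrom][s - 1 : e]).upper()
    if len(spliced) % 3 != 0:
        return "unknown"
    if spliced[offset] != ref:
        return "unknown"
    if transcript.strand == "-":
        cds_seq = spliced.translate(_COMPLEMENT)[::-1]
        index = len(spliced) - 1 - offset
        alt_base = alt.translate(_COMPLEMENT)
    else:
        cds_seq = spliced
        index = offset
        alt_base = alt
    ci = index // 3
    codon = cds_seq[3 * ci : 3 * ci + 3]
    mutated = codon[: index % 3] + alt_base + codon[index % 3 + 1 :]
    if any(b not in "ACGT" for b in codon):
        return "unknown"
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def assign_category(
    site: tuple,
    genes: GeneIndex,
    reference: Fasta | None = None,
    config: PipelineConfig | None = None,
) -> AnnotationRecord:
    """Assign one functional category (and coding effect) to a site.

    Precedence when several features match: exonic > UTR5 > UTR3 >
    intronic > ncRNA_exonic > ncRNA_intronic > upstream/downstream >
    intergenic; among equal-priority genes the nearest wins, ties broken
    by the smaller gene id.
    """
    cfg = config or PipelineConfig()
    chrom, pos, ref, alt = site
    if chrom not in genes.trees and chrom not in genes.by_chrom:
        # a chromosome with no genes is legal only if the reference knows it
        if reference is not None and chrom not in reference:
            raise ValueError(f"unknown chromosome {chrom!r}")
    ref_mismatch = False
    if reference is not None:
        if chrom not in reference:
            raise ValueError(f"unknown chromosome {chrom!r}")
        actual = str(reference[chrom][pos - 1]).upper()
        ref_mismatch = actual != ref

    containing = genes.containing(chrom, pos)
    if containing:
        scored = sorted(
            ((CATEGORY_PRIORITY.index(_internal_category(g, pos)), g.gene_id, g) for g in containing)
        )
        _prio, _gid, gene = scored[0]
        category = _internal_category(gene, pos)
        effect = "not_applicable"
        if category == "exonic":
            effect = "unknown"
            if reference is not None:
                for t in gene.transcripts:
                    if _in_any(pos, t.cds):
                        effect = coding_effect(site, t, reference)
                        break
        return AnnotationRecord(site, category, effect, gene.gene_id, 0, ref_mismatch)

    near = genes.within(chrom, pos, cfg.near_gene_bp)
    if near:
        sides = {}
        for g in near:
            sides.setdefault(g.side(pos), []).append(g)
        nearest = near[0]
        distance = nearest.boundary_distance(pos)
        if "upstream" in sides and "downstream" in sides:
            # requires two distinct genes, guaranteed: a gene has one side
            category = "upstream;downstream"
        else:
            category = nearest.side(pos)
        return AnnotationRecord(site, category, "not_applicable", nearest.gene_id, distance, ref_mismatch)

    nd = genes.nearest_distance(chrom, pos)
    return AnnotationRecord(
        site, "intergenic", "not_applicable", None, nd if nd is not None else -1, ref_mismatch
    )


def annotate_sites(
    sites: Sequence[tuple],
    genes: GeneIndex,
    reference: Fasta | None = None,
    config: PipelineConfig | None = None,
) -> list:
    return [assign_category(site, genes, reference, config) for site in sites]


def attach_to_genes(
    diffs: Sequence,
    annotations: Sequence[AnnotationRecord],
    genes: GeneIndex,
    config: PipelineConfig | None = None,
) -> tuple:
    """Attach SNVs to every gene within the 5 kb window.

    diffs may be DifferentialSNVs or plain (chrom, pos, ref, alt) sites;
    annotations must be parallel to diffs. Returns (assignments,
    retained_count) where assignments is a list of (site, annotation,
    gene_id, distance) and retained_count the number of SNVs attached to
    at least one gene.
    """
    cfg = config or PipelineConfig()
    ann_by_site = {a.site: a for a in annotations}
    assignments = []
    retained = 0
    for d in diffs:
        site = d if isinstance(d, tuple) else (d.chromosome, d.position, d.ref, d.alt)
        ann = ann_by_site[site]
        hits = genes.within(site[0], site[1], cfg.gene_window_bp)
        if hits:
            retained += 1
        for g in hits:
            assignments.append((site, ann, g.gene_id, g.boundary_distance(site[1])))
    return assignments, retained


@dataclass
class CategorySummary:
    """Per-category counts and half-up percentages of an annotated SNV set."""

    category_counts: dict
    effect_counts: dict
    total: int

    @classmethod
    def from_counts(cls, category_counts: dict, effect_counts: dict | None = None) -> "CategorySummary":
        counts = dict(category_counts)
        effects = dict(effect_counts or {})
        if effects and "exonic" not in counts:
            counts["exonic"] = sum(effects.values())
        return cls(counts, effects, sum(counts.values()))

    @property
    def percentages(self) -> dict:
        return {
            cat: round_half_up(100.0 * n / self.total, 2) for cat, n in self.category_counts.items()
        }

    def to_rows(self) -> list:
        rows = []
        for cat in CATEGORIES:
            if cat in self.category_counts:
                rows.append((cat, self.category_counts[cat], self.percentages[cat]))
                if cat == "exonic":
                    for eff in EXONIC_EFFECTS:
                        if eff in self.effect_counts:
                            rows.append((f"  {eff}", self.effect_counts[eff], ""))
        return rows

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["category", "count", "percentage"])
            for row in self.to_rows():
                w.writerow(row)
            w.writerow(["total", self.total, "100.00" if self.total else ""])


def summarize_categories(annotations: Sequence[AnnotationRecord]) -> CategorySummary:
    """Tabulate category counts (exonic broken down by effect)."""
    if not annotations:
        raise ValueError("summarize_categories requires at least one annotation")
    counts: dict = {}
    effects: dict = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
        if a.category == "exonic":
            effects[a.exonic_effect] = effects.get(a.exonic_effect, 0) + 1
    return CategorySummary(counts, effects, len(annotations))


def write_annotation_tsv(annotations: Sequence[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["chromosome", "position", "ref", "alt", "category", "exonic_effect", "gene", "distance_bp", "ref_mismatch"]
        )
        for a in annotations:
            chrom, pos, ref, alt = a.site
            w.writerow(
                [chrom, pos, ref, alt, a.category, a.exonic_effect, a.gene_id or ".", a.distance_bp, int(a.ref_mismatch)]
            )
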