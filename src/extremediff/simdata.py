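"""Self-consistent synthetic study generator with known ground truth.

Emulates the statistical structure the pipeline assumes: a small
multi-chromosome reference with non-overlapping gene models (coding
genes with start/stop codons and in-frame CDS; ncRNA genes), eight
diploid samples in four sib families, background SNVs independent of
the high/low labels, planted opposite-fixed sites with recorded alleles
and intended categories, per-call quality metrics with a configurable
failure fraction, and gene-set / genetic-map / QTL files in which every
planted candidate gene has a nearby QTL peak and membership in a
whitelisted pathway.

Everything derives from SimConfig.seed; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from extremediff._util import chrom_sort_key
from extremediff.annotator import GeneModel, Transcript
from extremediff.config import SimConfig
from extremediff.enrichment import GeneSet, write_gmt
from extremediff.prioritizer import GeneticMap, QTLRecord, interpolate_cM, write_qtl_csv

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODONS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: minimum span-to-span gap so every site is within 5 kb of at most one gene
GENE_GAP_BP = 12_000
_EDGE_MARGIN = 15_000

#: categories cycled over the planted candidate-gene SNVs
_CANDIDATE_CATEGORIES = ("exonic", "UTR5", "UTR3", "upstream", "downstream")


class SizingError(ValueError):
    """The requested genome cannot host the requested features."""


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one simulated study."""

    planted_sites: tuple  # ((chrom, pos, high_allele, low_allele, category), ...)
    planted_candidate_genes: tuple

    def validate(self, reference: dict) -> None:
        for chrom, pos, high, low, _cat in self.planted_sites:
            if chrom not in reference:
                raise ValueError(f"planted site on unknown chromosome {chrom}")
            if not 1 <= pos <= len(reference[chrom]):
                raise ValueError(f"planted site {chrom}:{pos} out of bounds")
            if high == low:
                raise ValueError("planted alleles must differ")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["chromosome", "position", "high_allele", "low_allele", "category", "candidate_gene"])
            for chrom, pos, high, low, cat in self.planted_sites:
                w.writerow([chrom, pos, high, low, cat, ""])
            for g in self.planted_candidate_genes:
                w.writerow(["", "", "", "", "", g])

    @classmethod
    def from_csv(cls, path: str | Path) -> "TruthTable":
        sites, genes = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if row["candidate_gene"]:
                    genes.append(row["candidate_gene"])
                else:
                    sites.append(
                        (row["chromosome"], int(row["position"]), row["high_allele"],
                         row["low_allele"], row["category"])
                    )
        return cls(tuple(sites), tuple(genes))


@dataclass
class Cohort:
    """In-memory simulated call set for the eight samples."""

    sites: list  # [(chrom, pos, ref, alt)]
    samples: list
    # calls[sample][site_index] = (state, base_quality, depth, alt_reads) or None
    calls: dict
    contig_lengths: dict


# ---------------------------------------------------------------- reference


def _build_coding_gene(rng, gene_id: str, chrom: str, strand: str, cursor: int) -> tuple:
    """Return (GeneModel, designed CDS in transcript orientation)."""
    u5 = int(rng.integers(60, 200))
    u3 = int(rng.integers(60, 200))
    n_codons = int(rng.integers(50, 150))  # incl. start and stop
    cds_len = 3 * n_codons
    n_exons = int(rng.integers(1, 4))
    # split CDS into n_exons chunks of >= 6 bp
    cuts = sorted(rng.choice(np.arange(2, n_codons - 2), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0, *[3 * c for c in cuts], cds_len]
    cds_parts = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(200, 1500)) for _ in range(n_exons - 1)]

    # transcript-order segments
    segments = [("utr5", u5)]
    for i, part in enumerate(cds_parts):
        segments.append(("cds", part))
        if i < len(introns):
            segments.append(("intron", introns[i]))
    segments.append(("utr3", u3))
    if strand == "-":
        segments = segments[::-1]

    pos = cursor
    placed = []  # (kind, start, end) ascending
    for kind, length in segments:
        placed.append((kind, pos, pos + length - 1))
        pos += length
    start, end = cursor, pos - 1

    cds_iv = tuple((s, e) for k, s, e in placed if k == "cds")
    utr5_iv = tuple((s, e) for k, s, e in placed if k == "utr5")
    utr3_iv = tuple((s, e) for k, s, e in placed if k == "utr3")
    # exons: maximal runs of non-intron segments
    exons = []
    for kind, s, e in placed:
        if kind == "intron":
            continue
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))

    designed = "ATG" + "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n_codons - 2)) + str(rng.choice(_STOP_CODONS))
    transcript = Transcript(f"{gene_id}.t1", chrom, strand, tuple(exons), cds_iv, utr5_iv, utr3_iv)
    gene = GeneModel(gene_id, chrom, strand, start, end, "coding", (transcript,))
    return gene, designed


def _build_ncrna_gene(rng, gene_id: str, chrom: str, strand: str, cursor: int) -> GeneModel:
    n_exons = int(rng.integers(1, 3))
    pos = cursor
    exons = []
    for i in range(n_exons):
        length = int(rng.integers(100, 500))
        exons.append((pos, pos + length - 1))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(200, 800))
    transcript = Transcript(f"{gene_id}.t1", chrom, strand, tuple(exons), (), (), ())
    return GeneModel(gene_id, chrom, strand, cursor, pos - 1, "ncRNA", (transcript,))


def simulate_reference(config: SimConfig) -> tuple:
    """Generate the reference (dict chrom -> bytearray) and gene models.

    Genes are non-overlapping with >= 12 kb span-to-span gaps; every
    coding CDS starts with ATG, ends with a stop codon, has length
    divisible by 3 and no internal stop, written into the reference in
    strand orientation.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    reference = {
        c: bytearray(
            rng.choice(_BASES, size=config.chromosome_length_bp).tobytes()
        )
        for c in chrom_names
    }

    n_nc = round(config.n_genes * config.fraction_noncoding_genes)
    nc_indices = set(
        int(i) for i in rng.choice(config.n_genes, size=n_nc, replace=False)
    ) if n_nc else set()

    cursors = {c: _EDGE_MARGIN for c in chrom_names}
    genes = []
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{gi + 1:04d}"
        if gi in nc_indices:
            gene = _build_ncrna_gene(rng, gene_id, chrom, strand, cursors[chrom])
            designed = None
        else:
            gene, designed = _build_coding_gene(rng, gene_id, chrom, strand, cursors[chrom])
        if gene.end > config.chromosome_length_bp - _EDGE_MARGIN:
            raise SizingError(
                f"{chrom} too short at gene {gene_id}: need end {gene.end}, "
                f"have {config.chromosome_length_bp - _EDGE_MARGIN}"
            )
        if designed is not None:
            _write_cds(reference[chrom], gene.transcripts[0], designed)
        genes.append(gene)
        cursors[chrom] = gene.end + 1 + GENE_GAP_BP + int(rng.integers(0, 3001))
    return reference, genes


def _write_cds(seq: bytearray, transcript: Transcript, designed: str) -> None:
    """Write the designed CDS into the genome in strand orientation."""
    if transcript.strand == "-":
        genomic = designed.translate(_COMPLEMENT)[::-1]
    else:
        genomic = designed
    i = 0
    for s, e in transcript.cds:
        n = e - s + 1
        seq[s - 1 : e] = genomic[i : i + n].encode()
        i += n
    assert i == len(genomic)


def write_reference_fasta(reference: dict, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference, key=chrom_sort_key):
            fh.write(f">{chrom}\n")
            seq = reference[chrom].decode() if isinstance(reference[chrom], (bytes, bytearray)) else str(reference[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], reference: dict, path: str | Path) -> None:
    src = "extremediff_sim"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(reference, key=chrom_sort_key):
            fh.write(f"##sequence-region {chrom} 1 {len(reference[chrom])}\n")
        for gene in sorted(genes, key=lambda g: (chrom_sort_key(g.chromosome), g.start)):
            biotype = "protein_coding" if gene.biotype == "coding" else "ncRNA"
            fh.write(
                "\t".join(
                    [gene.chromosome, src, "gene", str(gene.start), str(gene.end), ".",
                     gene.strand, ".", f"ID={gene.gene_id};biotype={biotype};Name={gene.gene_id}"]
                )
                + "\n"
            )
            for t in gene.transcripts:
                ttype = "mRNA" if gene.biotype == "coding" else "ncRNA"
                fh.write(
                    "\t".join(
                        [gene.chromosome, src, ttype, str(gene.start), str(gene.end), ".",
                         gene.strand, ".", f"ID={t.transcript_id};Parent={gene.gene_id}"]
                    )
                    + "\n"
                )
                for s, e in t.exons:
                    fh.write(
                        "\t".join([gene.chromosome, src, "exon", str(s), str(e), ".", gene.strand, ".",
                                   f"Parent={t.transcript_id}"]) + "\n"
                    )
                # CDS phase accumulates in transcript (5'->3') order
                cds_tx = t.cds if gene.strand == "+" else t.cds[::-1]
                cum = 0
                phases = {}
                for s, e in cds_tx:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s + 1
                for s, e in t.cds:
                    fh.write(
                        "\t".join([gene.chromosome, src, "CDS", str(s), str(e), ".", gene.strand,
                                   str(phases[(s, e)]), f"Parent={t.transcript_id}"]) + "\n"
                    )
                for s, e in t.utr5:
                    fh.write(
                        "\t".join([gene.chromosome, src, "five_prime_UTR", str(s), str(e), ".", gene.strand, ".",
                                   f"Parent={t.transcript_id}"]) + "\n"
                    )
                for s, e in t.utr3:
                    fh.write(
                        "\t".join([gene.chromosome, src, "three_prime_UTR", str(s), str(e), ".", gene.strand, ".",
                                   f"Parent={t.transcript_id}"]) + "\n"
                    )


# ------------------------------------------------------------------ cohort

FAMILY_DESIGN = tuple((f"family{i}", f"high{i}", f"low{i}") for i in range(1, 5))


def write_design_csv(design: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["family_id", "high_sample", "low_sample"])
        for fam, high, low in design:
            w.writerow([fam, high, low])


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _pick_candidate_site(rng, gene: GeneModel, category: str) -> int:
    """A 1-based position realising `category` for this gene."""
    t = gene.transcripts[0]
    if category == "exonic":
        # midpoint of the longest CDS interval: always an interior codon
        lengths = [e - s + 1 for s, e in t.cds]
        s, e = t.cds[int(np.argmax(lengths))]
        return (s + e) // 2
    if category == "UTR5":
        s, e = t.utr5[0]
        return (s + e) // 2
    if category == "UTR3":
        s, e = t.utr3[0]
        return (s + e) // 2
    d = int(rng.integers(100, 901))
    # upstream is the 5' side: left of the span on +, right on -
    pos_is_left = (category == "upstream") == (gene.strand == "+")
    return gene.start - d if pos_is_left else gene.end + d


def simulate_cohort(config: SimConfig, reference: dict, genes: Sequence[GeneModel]) -> tuple:
    """Simulate the eight-sample call set.

    Returns (cohort, design, truth). Planted differential sites are
    homozygous for one allele in all high samples and for the other in
    all low samples; background genotypes are drawn independently of
    the labels and re-drawn if they would mimic a differential site (or
    carry no variant at all).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    design = FAMILY_DESIGN
    samples = [s for _f, h, l in design for s in (h, l)]
    high_samples = [h for _f, h, _l in design]

    coding = [g for g in genes if g.biotype == "coding"]
    if config.n_planted_candidate_genes > len(coding):
        raise SizingError("not enough coding genes for the requested candidates")
    cand_idx = sorted(rng.choice(len(coding), size=config.n_planted_candidate_genes, replace=False))
    candidates = [coding[int(i)] for i in cand_idx]
    cand_ids = {g.gene_id for g in candidates}

    used: set = set()
    planted = []  # (chrom, pos, ref, alt, high_allele, low_allele, category)

    def plant(chrom: str, pos: int, category: str) -> None:
        ref = chr(reference[chrom][pos - 1])
        alt = _other_base(rng, ref)
        high_is_ref = bool(rng.random() < 0.5)
        high, low = (ref, alt) if high_is_ref else (alt, ref)
        planted.append((chrom, pos, ref, alt, high, low, category))
        used.add((chrom, pos))

    for i, gene in enumerate(candidates):
        category = _CANDIDATE_CATEGORIES[i % len(_CANDIDATE_CATEGORIES)]
        pos = _pick_candidate_site(rng, gene, category)
        plant(gene.chromosome, pos, category)

    # remaining planted sites: alternate intronic / deep intergenic
    n_rest = config.n_planted_differential - config.n_planted_candidate_genes
    intron_hosts = [
        g for g in coding
        if g.gene_id not in cand_ids and len(g.transcripts[0].exons) >= 2
    ]
    gaps = _intergenic_gaps(reference, genes)
    if n_rest > 0 and not intron_hosts and not gaps:
        raise SizingError("no room for the requested planted sites")
    gi = 0
    attempts = 0
    while len(planted) < config.n_planted_differential:
        attempts += 1
        if attempts > 50 * config.n_planted_differential:
            raise SizingError("requested planted sites exceed available positions")
        if len(planted) % 2 == 0 and intron_hosts:
            host = intron_hosts[gi % len(intron_hosts)]
            gi += 1
            t = host.transcripts[0]
            k = int(rng.integers(0, len(t.exons) - 1))
            lo, hi = t.exons[k][1] + 1, t.exons[k + 1][0] - 1
            pos = int(rng.integers(lo, hi + 1))
            if (host.chromosome, pos) in used:
                continue
            plant(host.chromosome, pos, "intronic")
        else:
            chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
            pos = int(rng.integers(lo, hi + 1))
            if (chrom, pos) in used:
                continue
            plant(chrom, pos, "intergenic")

    # background sites, genotypes independent of group labels
    chrom_names = sorted(reference, key=chrom_sort_key)
    background = []  # (chrom, pos, ref, alt, states per sample)
    while len(background) < config.n_background_snvs:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(1, len(reference[chrom]) + 1))
        if (chrom, pos) in used:
            continue
        ref = chr(reference[chrom][pos - 1])
        alt = _other_base(rng, ref)
        f = float(rng.uniform(0.1, 0.9))
        while True:
            states = []
            for _s in samples:
                u = rng.random()
                if u < config.het_rate:
                    states.append(1)
                elif rng.random() < f:
                    states.append(2)
                else:
                    states.append(0)
            if all(s == 0 for s in states):
                continue  # invisible site: no sample carries the variant
            hi = [states[samples.index(h)] for h in high_samples]
            lo = [states[i] for i, s in enumerate(samples) if s not in high_samples]
            if (
                hi[0] in (0, 2)
                and all(x == hi[0] for x in hi)
                and lo[0] in (0, 2)
                and all(x == lo[0] for x in lo)
                and hi[0] != lo[0]
            ):
                continue  # would mimic a planted differential site
            break
        used.add((chrom, pos))
        background.append((chrom, pos, ref, alt, states))

    sites = []
    site_states = []  # per-site list of per-sample state codes
    for chrom, pos, ref, alt, high, low, _cat in planted:
        sites.append((chrom, pos, ref, alt))
        hs = 0 if high == ref else 2
        ls = 2 - hs
        site_states.append([hs if s in high_samples else ls for s in samples])
    for chrom, pos, ref, alt, states in background:
        sites.append((chrom, pos, ref, alt))
        site_states.append(states)

    order = sorted(range(len(sites)), key=lambda i: (chrom_sort_key(sites[i][0]), sites[i][1]))
    sites = [sites[i] for i in order]
    site_states = [site_states[i] for i in order]

    calls = {s: [None] * len(sites) for s in samples}
    for i in range(len(sites)):
        for j, s in enumerate(samples):
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                continue
            state = site_states[i][j]
            fail = config.filter_fail_rate > 0 and rng.random() < config.filter_fail_rate
            calls[s][i] = _draw_metrics(rng, config, state, fail)

    truth = TruthTable(
        planted_sites=tuple(
            (chrom, pos, high, low, cat) for chrom, pos, _r, _a, high, low, cat in sorted(
                planted, key=lambda p: (chrom_sort_key(p[0]), p[1])
            )
        ),
        planted_candidate_genes=tuple(sorted(cand_ids)),
    )
    truth.validate(reference)
    cohort = Cohort(
        sites=sites,
        samples=samples,
        calls=calls,
        contig_lengths={c: len(reference[c]) for c in chrom_names},
    )
    return cohort, design, truth


def _intergenic_gaps(reference: dict, genes: Sequence[GeneModel]) -> list:
    """Regions > 5 kb from every gene span (and 1 kb inside chromosome ends)."""
    margin = 5_001
    gaps = []
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(reference, key=chrom_sort_key):
        spans = sorted((g.start, g.end) for g in by_chrom.get(chrom, []))
        prev_end = 0
        for s, e in spans:
            lo, hi = prev_end + margin, s - margin
            if hi - lo > 100:
                gaps.append((chrom, lo, hi))
            prev_end = e
        lo, hi = prev_end + margin, len(reference[chrom]) - 1_000
        if hi - lo > 100:
            gaps.append((chrom, lo, hi))
    return gaps


def _draw_metrics(rng, config: SimConfig, state: int, fail: bool) -> tuple:
    """(state_code, base_quality, depth, alt_reads) for one call."""
    depth = int(np.clip(rng.poisson(config.depth_mean), 5, 99))
    bq = int(np.clip(round(rng.normal(config.base_quality_mean, 3.0)), 20, 60))
    if state == 0:
        alt = 0
    elif state == 2:
        alt = depth
    else:
        alt = int(np.clip(rng.binomial(depth, 0.5), 4, depth - 1))
    if fail:
        modes = ["bq", "depth"] + (["alt"] if state in (1, 2) else [])
        mode = modes[int(rng.integers(0, len(modes)))]
        if mode == "bq":
            bq = int(rng.integers(5, 20))
        elif mode == "depth":
            depth = int(rng.integers(100, 150))
            alt = depth if state == 2 else (depth // 2 if state == 1 else 0)
        else:
            alt = int(rng.integers(0, 4))
    return (state, bq, depth, alt)


_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _vcf_header(contig_lengths: dict, samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(contig_lengths, key=chrom_sort_key):
        header.contigs.add(chrom, length=contig_lengths[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depth per allele")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for s in samples:
        header.add_sample(s)
    return header


def write_cohort_vcfs(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write one VCF per sample plus a merged cohort VCF; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for s in cohort.samples:
        path = out_dir / f"{s}.vcf"
        header = _vcf_header(cohort.contig_lengths, [s])
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for i, (chrom, pos, ref, alt) in enumerate(cohort.sites):
                call = cohort.calls[s][i]
                if call is None:
                    continue
                state, bq, depth, ad = call
                rec = vf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt), qual=float(bq))
                rec.samples[s]["GT"] = _GT[state]
                rec.samples[s]["AD"] = (depth - ad, ad)
                rec.samples[s]["DP"] = depth
                vf.write(rec)
        paths[s] = path

    merged = out_dir / "cohort.vcf"
    header = _vcf_header(cohort.contig_lengths, cohort.samples)
    with pysam.VariantFile(str(merged), "w", header=header) as vf:
        for i, (chrom, pos, ref, alt) in enumerate(cohort.sites):
            quals = [cohort.calls[s][i][1] for s in cohort.samples if cohort.calls[s][i] is not None]
            if not quals:
                continue
            rec = vf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), qual=float(min(quals))
            )
            for s in cohort.samples:
                call = cohort.calls[s][i]
                if call is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    state, _bq, depth, ad = call
                    rec.samples[s]["GT"] = _GT[state]
                    rec.samples[s]["AD"] = (depth - ad, ad)
                    rec.samples[s]["DP"] = depth
            vf.write(rec)
    paths["cohort"] = merged
    return paths


# ------------------------------------------------------- annotation resources


def simulate_annotation_resources(
    config: SimConfig, genes: Sequence[GeneModel], truth: TruthTable
) -> tuple:
    """Gene sets, genetic map and QTL table consistent with the truth.

    The genetic map has 5 strictly increasing anchors per chromosome at
    roughly 1 cM/Mb with per-segment jitter. Every planted candidate
    gene gets a QTL whose peak lies within 1 cM of the gene's
    interpolated start position; decoy QTLs are placed >= 3 cM from
    every gene. One gene set carries a trait-relevance keyword label,
    one a whitelisted pathway label (both containing all planted
    candidates), and the rest are decoys.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    coding = [g for g in genes if g.biotype == "coding"]
    if len(coding) < config.n_planted_candidate_genes + 5:
        raise SizingError("too few coding genes for the requested gene sets")
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    anchors = {}
    for chrom in sorted({g.chromosome for g in genes} | set(by_chrom), key=chrom_sort_key):
        L = config.chromosome_length_bp
        bps = [1, L // 4, L // 2, 3 * L // 4, L]
        cms = [0.0]
        for i in range(1, len(bps)):
            rate = float(rng.uniform(0.8, 1.2))  # cM per Mb
            cms.append(cms[-1] + rate * (bps[i] - bps[i - 1]) / 1e6)
        anchors[chrom] = list(zip(bps, cms))
    genetic_map = GeneticMap(anchors)

    gene_cm = {
        g.gene_id: interpolate_cM(genetic_map, g.chromosome, g.start) for g in genes
    }
    traits = ("PP", "PY", "FP", "FY")
    qtls = []
    gene_by_id = {g.gene_id: g for g in genes}
    for i, gid in enumerate(truth.planted_candidate_genes):
        g = gene_by_id[gid]
        cm = gene_cm[gid]
        offset = float(rng.uniform(0.1, 0.7)) * (1 if rng.random() < 0.5 else -1)
        peak = max(0.0, cm + offset)
        half = float(rng.uniform(1.0, 5.0))
        qtls.append(
            QTLRecord(
                chromosome=g.chromosome,
                trait=traits[i % 4],
                ci_start_cM=max(0.0, peak - half),
                ci_end_cM=peak + half,
                peaks_cM=(round(peak, 4),),
                source=f"sim_study_{i + 1}",
            )
        )
    # decoy QTLs: peaks >= 3 cM from every gene on the chromosome
    for j, chrom in enumerate(sorted(by_chrom, key=chrom_sort_key)):
        cms = [gene_cm[g.gene_id] for g in by_chrom[chrom]]
        peak = round(max(cms) + 3.0 + float(rng.uniform(0.5, 2.0)), 4)
        qtls.append(
            QTLRecord(
                chromosome=chrom,
                trait=traits[j % 4],
                ci_start_cM=max(0.0, peak - 2.0),
                ci_end_cM=peak + 2.0,
                peaks_cM=(peak,),
                source=f"sim_decoy_{j + 1}",
            )
        )

    cand = list(truth.planted_candidate_genes)
    non_cand = [g.gene_id for g in coding if g.gene_id not in cand]
    fillers = [non_cand[int(i)] for i in rng.choice(len(non_cand), size=min(5, len(non_cand)), replace=False)]
    gene_sets = [
        GeneSet("SIM:GO:0001", "lipid metabolic process", "GO", frozenset(cand + fillers[:3])),
        GeneSet("SIM:KEGG:0001", "PPAR signaling pathway", "KEGG", frozenset(cand + fillers[3:5])),
    ]
    decoy_labels = ["cell cycle", "DNA repair", "ribosome biogenesis", "ion transport", "axon guidance"]
    all_ids = [g.gene_id for g in genes]
    for di, label in enumerate(decoy_labels):
        size = min(8, len(all_ids))
        members = frozenset(all_ids[int(i)] for i in rng.choice(len(all_ids), size=size, replace=False))
        gene_sets.append(GeneSet(f"SIM:GO:{1000 + di}", label, "GO", members))
    return gene_sets, genetic_map, qtls


# ----------------------------------------------------------------- study


def simulate_study(config: SimConfig, out_dir: str | Path) -> dict:
    """Run the full simulation and write every artifact; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference, genes = simulate_reference(config)
    cohort, design, truth = simulate_cohort(config, reference, genes)
    gene_sets, genetic_map, qtls = simulate_annotation_resources(config, genes, truth)

    paths = {
        "reference": out_dir / "reference.fa",
        "gff": out_dir / "genes.gff3",
        "design": out_dir / "design.csv",
        "truth": out_dir / "truth.csv",
        "gmt": out_dir / "gene_sets.gmt",
        "map": out_dir / "genetic_map.csv",
        "qtl": out_dir / "qtl.csv",
    }
    write_reference_fasta(reference, paths["reference"])
    write_gff3(genes, reference, paths["gff"])
    vcf_paths = write_cohort_vcfs(cohort, out_dir / "vcf")
    write_design_csv(design, paths["design"])
    truth.to_csv(paths["truth"])
    write_gmt(gene_sets, paths["gmt"])
    genetic_map.to_csv(paths["map"])
    write_qtl_csv(qtls, paths["qtl"])
    paths["vcfs"] = {s: p for s, p in vcf_paths.items() if s != "cohort"}
    paths["cohort_vcf"] = vcf_paths["cohort"]
    return paths
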