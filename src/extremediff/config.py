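"""Configuration objects for the simulation and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the design the pipeline targets: eight diploid
    samples in four sib families (one extreme-high and one extreme-low
    member each), biallelic SNVs called per sample with base quality,
    depth and alt-supporting read counts, and a small set of "planted"
    opposite-fixed sites whose positions and alleles are recorded in a
    truth table.

    Parameters
    ----------
    n_chromosomes, chromosome_length_bp
        Size of the synthetic genome.
    n_genes
        Gene models placed non-overlapping with >= 12 kb gaps so the
        1 kb near-gene and 5 kb attachment windows are unambiguous.
    fraction_noncoding_genes
        Fraction of genes emitted with an ncRNA biotype (no CDS).
    n_background_snvs
        Sites with genotypes drawn independently of the high/low labels;
        never opposite-fixed across all four families.
    n_planted_differential
        Opposite-fixed sites: all high samples homozygous for one allele,
        all low samples homozygous for the other.
    n_planted_candidate_genes
        Genes given a planted differential SNV in a regulatory/exonic
        category plus a nearby QTL peak, i.e. the ground-truth answer of
        the full pipeline.
    het_rate
        Per-cell heterozygote probability at background sites.
    missing_rate
        Per-cell probability that a call is omitted from a sample's VCF.
    depth_mean
        Mean per-call read depth (Poisson); 8.1 matches a typical ~8x
        whole-genome resequencing design.
    base_quality_mean
        Mean per-call phred base quality.
    filter_fail_rate
        Fraction of calls deliberately violating one of the call-quality
        thresholds, to exercise the filtering stage.
    seed
        Single seed for every random draw.
    """

    n_chromosomes: int = 3
    chromosome_length_bp: int = 1_000_000
    n_genes: int = 60
    fraction_noncoding_genes: float = 0.1
    n_background_snvs: int = 2_000
    n_planted_differential: int = 50
    n_planted_candidate_genes: int = 5
    het_rate: float = 0.3
    missing_rate: float = 0.02
    depth_mean: float = 8.1
    base_quality_mean: float = 30.0
    filter_fail_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chromosome_length_bp", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_background_snvs", "n_planted_differential", "n_planted_candidate_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("fraction_noncoding_genes", "het_rate", "missing_rate", "filter_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planted_candidate_genes > self.n_genes:
            raise ValueError("n_planted_candidate_genes exceeds n_genes")
        if self.n_planted_differential < self.n_planted_candidate_genes:
            raise ValueError("n_planted_differential must cover every planted candidate gene")
        if self.depth_mean <= 0 or self.base_quality_mean <= 0:
            raise ValueError("depth_mean and base_quality_mean must be positive")


#: the eight well-known protein/fat metabolism pathways rescued regardless
#: of enrichment significance
DEFAULT_WHITELIST = frozenset(
    {"mTOR", "insulin", "AMPK", "PPAR", "Jak-STAT", "PI3K-Akt", "MAPK", "TGF-β"}
)

DEFAULT_KEYWORDS = ("protein", "lipid", "fatty acid")


@dataclass
class PipelineConfig:
    """Thresholds and conventions of the analysis pipeline.

    min_base_quality / max_depth_exclusive / min_alt_reads_exclusive
        SNV-call acceptance: base quality >= 20, depth < 100, and, for a
        call carrying the alternate allele, more than 3 supporting reads.
    near_gene_bp
        Sites within this distance of a gene are upstream/downstream;
        farther, intergenic (1 kb convention).
    gene_window_bp
        SNV-to-gene attachment window for the gene-level analyses (5 kb).
    ora_alpha
        Raw-p significance threshold of the over-representation test.
    qtl_max_cM
        A candidate gene must lie strictly closer than this to a QTL peak.
    whitelist_pathways
        Pathway labels whose member genes are kept even when their set is
        not significantly enriched (case-insensitive substring match).
    relevance_keywords
        Keywords selecting significant sets considered trait-relevant.
    traits
        QTL trait codes considered (milk protein/fat percentage & yield).
    absent_means
        How to score a sample with no record at a union site: "missing"
        (single-sample VCFs cannot distinguish reference from no-data) or
        "hom_ref".
    gene_cm_from
        Physical coordinate interpolated into cM per gene: "start" or
        "midpoint".
    bh_correction
        Apply Benjamini-Hochberg to ORA p-values (off: raw p < alpha).
    """

    min_base_quality: float = 20.0
    max_depth_exclusive: int = 100
    min_alt_reads_exclusive: int = 3
    near_gene_bp: int = 1_000
    gene_window_bp: int = 5_000
    ora_alpha: float = 0.05
    qtl_max_cM: float = 1.0
    whitelist_pathways: frozenset = DEFAULT_WHITELIST
    relevance_keywords: tuple = DEFAULT_KEYWORDS
    traits: frozenset = frozenset({"PP", "PY", "FP", "FY"})
    absent_means: str = "missing"
    gene_cm_from: str = "start"
    bh_correction: bool = False

    def validate(self) -> None:
        if self.min_base_quality <= 0 or self.max_depth_exclusive <= 0:
            raise ValueError("call-filter thresholds must be positive")
        if self.min_alt_reads_exclusive < 0:
            raise ValueError("min_alt_reads_exclusive must be non-negative")
        if self.near_gene_bp <= 0 or self.gene_window_bp <= 0:
            raise ValueError("distance windows must be positive")
        if not 0.0 < self.ora_alpha < 1.0:
            raise ValueError("ora_alpha must lie in (0, 1)")
        if self.qtl_max_cM <= 0:
            raise ValueError("qtl_max_cM must be positive")
        if self.absent_means not in ("missing", "hom_ref"):
            raise ValueError("absent_means must be 'missing' or 'hom_ref'")
        if self.gene_cm_from not in ("start", "midpoint"):
            raise ValueError("gene_cm_from must be 'start' or 'midpoint'")
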