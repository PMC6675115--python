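"""Shared fixtures: simulated studies and a hand-built gene-model fixture."""

from __future__ import annotations

import numpy as np
import pytest

from extremediff.annotator import GeneIndex, GeneModel, Transcript
from extremediff.config import SimConfig
from extremediff.pipeline import run_pipeline
from extremediff.simdata import TruthTable, simulate_study


def pipeline_inputs(paths: dict) -> dict:
    return {
        "vcfs": paths["vcfs"],
        "design": paths["design"],
        "gff": paths["gff"],
        "fasta": paths["reference"],
        "gmt": paths["gmt"],
        "map": paths["map"],
        "qtl": paths["qtl"],
    }


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact noiseless study used by fast unit tests."""
    return SimConfig(
        n_chromosomes=2,
        chromosome_length_bp=400_000,
        n_genes=14,
        n_background_snvs=300,
        n_planted_differential=12,
        n_planted_candidate_genes=3,
        missing_rate=0.0,
        filter_fail_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory) -> dict:
    return simulate_study(small_config, tmp_path_factory.mktemp("small_study"))


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    """Full-size noiseless study: 2,000 background SNVs, 50 planted sites,
    5 planted candidate genes across a 3 x 1 Mb genome."""
    return SimConfig(missing_rate=0.0, filter_fail_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config, tmp_path_factory) -> dict:
    return simulate_study(noiseless_config, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_study) -> TruthTable:
    return TruthTable.from_csv(noiseless_study["truth"])


@pytest.fixture(scope="session")
def noiseless_run(noiseless_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    report = run_pipeline(pipeline_inputs(noiseless_study), out)
    return report, out


# ------------------------------------------------- hand-built gene fixture


def _coding_gene(gene_id, chrom, strand, utr5, cds, utr3, exons):
    start = min(iv[0] for iv in exons)
    end = max(iv[1] for iv in exons)
    t = Transcript(f"{gene_id}.t1", chrom, strand, tuple(exons), tuple(cds), tuple(utr5), tuple(utr3))
    return GeneModel(gene_id, chrom, strand, start, end, "coding", (t,))


def _ncrna_gene(gene_id, chrom, strand, exons):
    start = min(iv[0] for iv in exons)
    end = max(iv[1] for iv in exons)
    t = Transcript(f"{gene_id}.t1", chrom, strand, tuple(exons), (), (), ())
    return GeneModel(gene_id, chrom, strand, start, end, "ncRNA", (t,))


@pytest.fixture(scope="session")
def gene_fixture():
    """20 gene models on one 200 kb chromosome, including overlapping genes,
    a gene pair < 2 kb apart (upstream;downstream territory) and both
    strands; returns (GeneIndex, genes, chrom, region_length)."""
    chrom = "chrT"
    genes = [
        # plain two-exon coding gene, + strand
        _coding_gene(
            "gA", chrom, "+",
            utr5=[(10_000, 10_199)],
            cds=[(10_200, 10_799), (11_400, 11_999)],
            utr3=[(12_000, 12_999)],
            exons=[(10_000, 10_799), (11_400, 12_999)],
        ),
        # minus-strand coding gene: UTR5 at the genomic right end
        _coding_gene(
            "gB", chrom, "-",
            utr5=[(22_800, 22_999)],
            cds=[(20_500, 21_099), (21_700, 22_799)],
            utr3=[(20_000, 20_499)],
            exons=[(20_000, 21_099), (21_700, 22_999)],
        ),
        # ncRNA with two exons
        _ncrna_gene("gC", chrom, "+", exons=[(26_000, 26_399), (27_000, 27_399)]),
        # overlapping pair: gE sits inside gD's intron
        _coding_gene(
            "gD", chrom, "+",
            utr5=[(30_000, 30_099)],
            cds=[(30_100, 30_999), (39_100, 39_999)],
            utr3=[(40_000, 40_499)],
            exons=[(30_000, 30_999), (39_100, 40_499)],
        ),
        _coding_gene(
            "gE", chrom, "+",
            utr5=[(32_000, 32_099)],
            cds=[(32_100, 33_299)],
            utr3=[(33_300, 33_499)],
            exons=[(32_000, 33_499)],
        ),
        # close pair for upstream;downstream: gF ends 50_000, gG starts 51_500
        _coding_gene(
            "gF", chrom, "+",
            utr5=[(48_000, 48_099)],
            cds=[(48_100, 49_599)],
            utr3=[(49_600, 50_000)],
            exons=[(48_000, 50_000)],
        ),
        _coding_gene(
            "gG", chrom, "+",
            utr5=[(51_500, 51_599)],
            cds=[(51_600, 52_799)],
            utr3=[(52_800, 52_999)],
            exons=[(51_500, 52_999)],
        ),
    ]
    rng = np.random.default_rng(2024)
    cursor = 60_000
    for i in range(13):
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = (cursor, cursor + 99)
        c1 = (cursor + 100, cursor + 699)
        c2 = (cursor + 1_200, cursor + 1_799)
        u3 = (cursor + 1_800, cursor + 1_999)
        genes.append(
            _coding_gene(
                f"g{i:02d}", chrom, strand,
                utr5=[u5], cds=[c1, c2], utr3=[u3],
                exons=[(u5[0], c1[1]), (c2[0], u3[1])],
            )
        )
        cursor += 2_000 + int(rng.integers(2_000, 9_000))
    assert len(genes) == 20
    return GeneIndex(genes), genes, chrom, 200_000
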