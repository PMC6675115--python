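"""Region annotation, coding effects, gene attachment and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from pyfaidx import Fasta

from extremediff.annotator import (
    CategorySummary,
    GeneIndex,
    GeneModel,
    Transcript,
    assign_category,
    attach_to_genes,
    coding_effect,
    summarize_categories,
)
from extremediff.config import PipelineConfig

_PRI = ["exonic", "UTR5", "UTR3", "intronic", "ncRNA_exonic", "ncRNA_intronic"]
_RC = str.maketrans("ACGT", "TGCA")


# ------------------------------------------------------ brute-force oracle


def oracle_category(pos, genes, near=1000):
    """Direct interval-membership scan over every gene and feature."""
    best = None
    for g in genes:
        if not g.start <= pos <= g.end:
            continue
        if g.biotype == "ncRNA":
            in_exon = any(s <= pos <= e for t in g.transcripts for s, e in t.exons)
            cat = "ncRNA_exonic" if in_exon else "ncRNA_intronic"
        else:
            cats = []
            for t in g.transcripts:
                if any(s <= pos <= e for s, e in t.cds):
                    cats.append("exonic")
                elif any(s <= pos <= e for s, e in t.utr5):
                    cats.append("UTR5")
                elif any(s <= pos <= e for s, e in t.utr3):
                    cats.append("UTR3")
                else:
                    cats.append("intronic")
            cat = min(cats, key=_PRI.index)
        key = (_PRI.index(cat), g.gene_id)
        if best is None or key < best[0]:
            best = (key, cat, g.gene_id)
    if best:
        return best[1], best[2]
    hits = []
    for g in genes:
        if g.start <= pos <= g.end:
            continue
        d = min(abs(pos - g.start), abs(pos - g.end))
        if d > near:
            continue
        left = pos < g.start
        side = ("upstream" if left else "downstream") if g.strand == "+" else (
            "downstream" if left else "upstream"
        )
        hits.append((d, g.gene_id, side))
    if not hits:
        return "intergenic", None
    hits.sort()
    if {s for _d, _g, s in hits} == {"upstream", "downstream"}:
        return "upstream;downstream", hits[0][1]
    return hits[0][2], hits[0][1]


class TestAssignCategory:
    def test_random_sites_match_oracle(self, gene_fixture):
        index, genes, chrom, length = gene_fixture
        rng = np.random.default_rng(99)
        positions = rng.integers(1, length + 1, size=1200)
        # add deliberate boundary and overlap probes
        probes = [
            9_000, 8_999,  # exactly 1 kb above gA's start, and 1 bp farther
            13_999, 14_000,  # 1 kb below gA's end
            32_500,  # inside gE's CDS, within gD's intron
            31_500,  # gD intron only
            50_700,  # between gF and gG: upstream;downstream
            26_100, 26_500,  # ncRNA exon / intron
        ]
        for pos in list(positions) + probes:
            rec = assign_category((chrom, int(pos), "A", "C"), index)
            cat, gene = oracle_category(int(pos), genes)
            assert (rec.category, rec.gene_id) == (cat, gene), pos

    def test_overlap_precedence_exonic_beats_intronic(self, gene_fixture):
        index, *_ = gene_fixture
        rec = assign_category(("chrT", 32_500, "A", "C"), index)
        assert rec.category == "exonic" and rec.gene_id == "gE"

    def test_upstream_downstream_requires_two_genes(self, gene_fixture):
        index, *_ = gene_fixture
        rec = assign_category(("chrT", 50_700, "A", "C"), index)
        assert rec.category == "upstream;downstream"
        assert rec.gene_id == "gF" and rec.distance_bp == 700

    def test_published_worked_examples(self):
        """Upstream/downstream distances of the worked candidate SNVs."""
        def span_gene(gene_id, start, end, strand):
            t = Transcript(f"{gene_id}.t1", "chr", strand, ((start, end),),
                           ((start, end),), (), ())
            return GeneModel(gene_id, "chr", strand, start, end, "coding", (t,))

        # + strand gene starting 81 bp beyond the SNV -> upstream, 81 bp
        g = span_gene("C3H1orf85", 14_558_546, 14_561_400, "+")
        rec = assign_category(("chr", 14_558_465, "T", "C"), GeneIndex([g]))
        assert (rec.category, rec.distance_bp) == ("upstream", 81)
        # - strand gene starting 819 bp beyond the SNV -> downstream
        g = span_gene("SNX7", 44_657_521, 44_775_833, "-")
        rec = assign_category(("chr", 44_656_702, "A", "G"), GeneIndex([g]))
        assert (rec.category, rec.distance_bp) == ("downstream", 819)
        # - strand gene ending 683 bp before the SNV -> upstream
        g = span_gene("MGEA5", 22_390_769, 22_417_775, "-")
        rec = assign_category(("chr", 22_418_458, "A", "G"), GeneIndex([g]))
        assert (rec.category, rec.distance_bp) == ("upstream", 683)

    def test_unknown_chromosome_raises(self, gene_fixture, tmp_path):
        index, *_ = gene_fixture
        fa = tmp_path / "r.fa"
        fa.write_text(">chrT\n" + "A" * 100 + "\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_category(("chrZ", 10, "A", "C"), index, Fasta(str(fa)))

    def test_reference_mismatch_flagged_not_dropped(self, gene_fixture, tmp_path):
        index, *_ = gene_fixture
        fa = tmp_path / "r.fa"
        fa.write_text(">chrT\n" + "A" * 1000 + "\n")
        rec = assign_category(("chrT", 10, "G", "C"), index, Fasta(str(fa)))
        assert rec.ref_mismatch and rec.category == "intergenic"


# ------------------------------------------------------------ coding effect


def _write_fasta(tmp_path, name, seq):
    path = tmp_path / f"{name}.fa"
    path.write_text(f">{name}\n{seq}\n")
    return Fasta(str(path))


def oracle_effect(seq, cds, strand, pos, alt):
    """Translate the whole reference and mutated CDS and compare."""
    spliced = "".join(seq[s - 1 : e] for s, e in cds)
    offset = 0
    for s, e in cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    mutated = spliced[:offset] + alt + spliced[offset + 1 :]
    if strand == "-":
        spliced = spliced.translate(_RC)[::-1]
        mutated = mutated.translate(_RC)[::-1]
        offset = len(spliced) - 1 - offset
    p_ref = str(Seq(spliced).translate())
    p_alt = str(Seq(mutated).translate())
    i = offset // 3
    if p_ref[i] == p_alt[i]:
        return "synonymous"
    if p_alt[i] == "*":
        return "stopgain"
    if p_ref[i] == "*":
        return "stoploss"
    return "nonsynonymous"


class TestCodingEffect:
    CDS_SEQ = "ATGGGATACTAA"  # Met-Gly-Tyr-stop

    def _transcript(self, strand, cds):
        return Transcript("t1", "c", strand, tuple(cds), tuple(cds), (), ())

    def test_synonymous_and_stop_examples(self, tmp_path):
        seq = "XXXXXXXXXX" + self.CDS_SEQ + "XXXXXXXXXX"
        seq = seq.replace("X", "G")
        fa = _write_fasta(tmp_path, "c", seq)
        t = self._transcript("+", [(11, 22)])
        # GGA -> GGC, third position of a 4-fold degenerate codon
        assert coding_effect(("c", 16, "A", "C"), t, fa) == "synonymous"
        # TAC -> TAA
        assert coding_effect(("c", 19, "C", "A"), t, fa) == "stopgain"
        # TAA -> TCA
        assert coding_effect(("c", 21, "A", "C"), t, fa) == "stoploss"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_substitutions_match_translation_oracle(self, tmp_path, strand):
        """Every single-base substitution at every CDS position equals the
        direct translate-both-codons lookup, on both strands and across
        a spliced (two-interval) CDS."""
        core = "ATGGGATACCCGTTTCACTGA"  # 7 codons
        genomic = core if strand == "+" else core.translate(_RC)[::-1]
        # split the CDS across an intron: intervals (11, 19) and (120, 131)
        seq = ["G"] * 200
        seq[10:19] = genomic[:9]
        seq[119:131] = genomic[9:]
        seq = "".join(seq)
        fa = _write_fasta(tmp_path, "c", seq)
        t = self._transcript(strand, [(11, 19), (120, 131)])
        for pos in list(range(11, 20)) + list(range(120, 132)):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = coding_effect(("c", pos, ref, alt), t, fa)
                assert got == oracle_effect(seq, t.cds, strand, pos, alt), (strand, pos, alt)

    def test_malformed_cds_and_mismatch_are_unknown(self, tmp_path):
        seq = "G" * 10 + self.CDS_SEQ + "G" * 10
        fa = _write_fasta(tmp_path, "c", seq)
        t_bad = self._transcript("+", [(11, 21)])  # length 11, not %3
        assert coding_effect(("c", 16, "A", "C"), t_bad, fa) == "unknown"
        t = self._transcript("+", [(11, 22)])
        assert coding_effect(("c", 16, "T", "C"), t, fa) == "unknown"  # ref mismatch

    def test_outside_cds_is_contract_violation(self, tmp_path):
        fa = _write_fasta(tmp_path, "c", "G" * 40)
        t = self._transcript("+", [(11, 22)])
        with pytest.raises(ValueError, match="not inside a CDS"):
            coding_effect(("c", 5, "G", "A"), t, fa)


# -------------------------------------------------------------- attachment


class TestAttachToGenes:
    def _annotate(self, sites, index):
        return [assign_category(s, index) for s in sites]

    def test_window_boundaries(self, gene_fixture):
        index, *_ = gene_fixture
        # gA spans 10_000-12_999; nothing else below it
        inside = ("chrT", 5_001, "A", "C")  # 4,999 bp from the start
        outside = ("chrT", 4_999, "A", "C")  # 5,001 bp from the start
        sites = [inside, outside]
        assignments, retained = attach_to_genes(sites, self._annotate(sites, index), index)
        attached = {s for s, *_r in assignments}
        assert inside in attached and outside not in attached
        assert retained == 1

    def test_retained_count_matches_all_pairs_distances(self, gene_fixture):
        index, genes, chrom, length = gene_fixture
        rng = np.random.default_rng(5)
        sites = [(chrom, int(p), "A", "C") for p in rng.integers(1, length + 1, size=100)]
        assignments, retained = attach_to_genes(sites, self._annotate(sites, index), index)
        expected = sum(
            1 for s in sites if any(g.boundary_distance(s[1]) <= 5_000 for g in genes)
        )
        assert retained == expected
        for site, _ann, gene_id, dist in assignments:
            g = next(g for g in genes if g.gene_id == gene_id)
            assert dist == g.boundary_distance(site[1]) <= 5_000


# --------------------------------------------------------------- summaries


class TestSummaries:
    def test_counts_partition_and_exonic_breakdown(self, gene_fixture, ):
        index, genes, chrom, length = gene_fixture
        rng = np.random.default_rng(8)
        sites = [(chrom, int(p), "A", "C") for p in rng.integers(1, length + 1, size=500)]
        anns = [assign_category(s, index) for s in sites]
        summary = summarize_categories(anns)
        assert sum(summary.category_counts.values()) == summary.total == 500
        assert sum(summary.effect_counts.values()) == summary.category_counts.get("exonic", 0)

    def test_single_category_is_100_percent(self):
        counts = {"intergenic": 7}
        s = CategorySummary.from_counts(counts)
        assert s.percentages["intergenic"] == 100.00

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories([])

    def test_half_up_percentage_rounding(self):
        s = CategorySummary.from_counts({"a": 1, "b": 7999})  # 0.0125 %
        assert s.percentages["a"] == 0.01
        s = CategorySummary.from_counts({"a": 1, "b": 799})  # 0.125 %
        assert s.percentages["a"] == 0.13
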