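"""Call-filter semantics and genotype-matrix assembly."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from extremediff.config import PipelineConfig
from extremediff.variant_filter import (
    CallRecord,
    GenotypeMatrix,
    build_matrix,
    iter_call_records,
    passes_call_filters,
    read_design,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _vcf(tmp_path, sample, rows):
    path = tmp_path / f"{sample}.vcf"
    body = "".join(
        f"chr1\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:AD:DP\t{gt}:{ra},{aa}:{ra + aa}\n"
        for pos, ref, alt, qual, gt, ra, aa in rows
    )
    path.write_text(VCF_HEADER.format(sample=sample) + body)
    return path


def _record(**kw):
    base = dict(
        chromosome="chr1", position=100, ref_allele="A", alt_allele="G",
        sample="s1", genotype="hom_alt", base_quality=30.0, depth=20, alt_reads=20,
    )
    base.update(kw)
    return CallRecord(**base)


class TestPassesCallFilters:
    @pytest.mark.parametrize(
        "bq,depth,alt,expected",
        [
            (20, 99, 4, True),  # boundary of all three criteria
            (19, 50, 10, False),  # quality below 20
            (30, 100, 10, False),  # depth not strictly below 100
            (30, 50, 3, False),  # needs > 3 alt-supporting reads
            (20.0, 1, 0, False),  # hom_alt with no support
        ],
    )
    def test_threshold_boundaries(self, bq, depth, alt, expected):
        rec = _record(base_quality=bq, depth=depth, alt_reads=alt)
        assert passes_call_filters(rec) is expected

    def test_missing_never_passes(self):
        rec = _record(genotype="missing", base_quality=60, depth=30, alt_reads=30)
        assert not passes_call_filters(rec)

    def test_hom_ref_screened_on_quality_and_depth_only(self):
        # a reference call asserts no alternate allele, so alt-read
        # support is not required of it
        assert passes_call_filters(_record(genotype="hom_ref", alt_reads=0))
        assert not passes_call_filters(_record(genotype="hom_ref", alt_reads=0, base_quality=10))
        assert not passes_call_filters(_record(genotype="hom_ref", alt_reads=0, depth=150))

    def test_random_records_match_per_record_oracle(self):
        rng = np.random.default_rng(42)
        n_pass = 0
        expected = 0
        for _ in range(1000):
            bq = float(rng.integers(0, 60))
            depth = int(rng.integers(1, 150))
            alt = int(rng.integers(0, depth + 1))
            state = ["het", "hom_alt"][int(rng.integers(0, 2))]
            rec = _record(genotype=state, base_quality=bq, depth=depth, alt_reads=alt)
            n_pass += passes_call_filters(rec)
            expected += bq >= 20 and depth < 100 and alt > 3
        assert n_pass == expected

    @given(
        bq=st.floats(0, 60), depth=st.integers(1, 150), frac=st.floats(0, 1),
        d_bq=st.floats(0, 10), d_depth=st.integers(0, 30), d_alt=st.integers(0, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_tightening_thresholds_is_monotone(self, bq, depth, frac, d_bq, d_depth, d_alt):
        rec = _record(genotype="het", base_quality=bq, depth=depth, alt_reads=int(frac * depth))
        loose = PipelineConfig()
        tight = PipelineConfig(
            min_base_quality=loose.min_base_quality + d_bq,
            max_depth_exclusive=max(1, loose.max_depth_exclusive - d_depth),
            min_alt_reads_exclusive=loose.min_alt_reads_exclusive + d_alt,
        )
        if passes_call_filters(rec, tight):
            assert passes_call_filters(rec, loose)


class TestBuildMatrix:
    def _design(self):
        return [(f"family{i}", f"h{i}", f"l{i}") for i in range(1, 5)]

    def test_identical_hom_alt_vcfs(self, tmp_path):
        rows = [(500, "A", "G", 40, "1/1", 0, 20)]
        design = self._design()
        vcfs = {s: _vcf(tmp_path, s, rows) for _f, h, l in design for s in (h, l)}
        m = build_matrix(vcfs, design)
        assert m.sites == [("chr1", 500, "A", "G")]
        assert (m.states == 2).all() and m.states.shape == (1, 8)

    def test_absent_sample_is_missing_by_default(self, tmp_path):
        rows = [(500, "A", "G", 40, "0/1", 10, 10)]
        design = self._design()
        vcfs = {}
        for _f, h, l in design:
            for s in (h, l):
                vcfs[s] = _vcf(tmp_path, s, rows if s != "l4" else [])
        m = build_matrix(vcfs, design)
        assert m.state(0, "l4") == "missing"
        assert m.state(0, "h1") == "het"
        m2 = build_matrix(vcfs, design, PipelineConfig(absent_means="hom_ref"))
        assert m2.state(0, "l4") == "hom_ref"

    def test_failing_record_demoted_to_missing(self, tmp_path):
        rows = [(500, "A", "G", 10, "1/1", 0, 20)]  # quality 10: fails
        design = self._design()
        vcfs = {s: _vcf(tmp_path, s, rows) for _f, h, l in design for s in (h, l)}
        m = build_matrix(vcfs, design)
        assert (m.states == -1).all()

    def test_conflicting_ref_alleles_raise(self, tmp_path):
        design = self._design()
        vcfs = {}
        for _f, h, l in design:
            for s in (h, l):
                ref = "A" if s != "l4" else "C"
                vcfs[s] = _vcf(tmp_path, s, [(500, ref, "G", 40, "1/1", 0, 20)])
        with pytest.raises(ValueError, match="conflicting ref"):
            build_matrix(vcfs, design)

    def test_sample_without_vcf_raises(self, tmp_path):
        design = self._design()
        vcfs = {s: _vcf(tmp_path, s, []) for _f, h, l in design[:3] for s in (h, l)}
        with pytest.raises(ValueError, match="no VCF"):
            build_matrix(vcfs, design)

    def test_order_invariance_and_oracle_counts(self, small_study):
        """Matrix dimensions and per-state counts equal a line-by-line
        re-parse of the VCF bodies with the same filter rules."""
        design = read_design(small_study["design"])
        vcfs = small_study["vcfs"]
        m = build_matrix(vcfs, design)
        reversed_paths = list(vcfs.values())[::-1]
        m_rev = build_matrix(reversed_paths, design)
        assert m.sites == m_rev.sites and (m.states == m_rev.states).all()

        # brute-force text parse, independent of pysam
        per_sample_calls = {}
        sites = set()
        for sample, path in vcfs.items():
            for line in open(path):
                if line.startswith("#"):
                    continue
                chrom, pos, _id, ref, alt, qual, _f, _i, _fmt, data = line.split("\t")
                gt, ad, dp = data.strip().split(":")
                _ra, aa = ad.split(",")
                state = {"0/0": "hom_ref", "0/1": "het", "1/1": "hom_alt"}[gt]
                ok = float(qual) >= 20 and int(dp) < 100 and (
                    state == "hom_ref" or int(aa) > 3
                )
                sites.add((chrom, int(pos), ref, alt))
                per_sample_calls[(sample, chrom, int(pos))] = state if ok else "missing"
        assert len(m.sites) == len(sites)
        for i, (chrom, pos, _ref, _alt) in enumerate(m.sites):
            for s in m.samples:
                expected = per_sample_calls.get((s, chrom, pos), "missing")
                assert m.state(i, s) == expected

    def test_matrix_tsv_roundtrip(self, tmp_path, small_study):
        design = read_design(small_study["design"])
        m = build_matrix(small_study["vcfs"], design)
        m.to_tsv(tmp_path / "m.tsv")
        m2 = GenotypeMatrix.from_tsv(tmp_path / "m.tsv")
        assert m.sites == m2.sites and m.samples == m2.samples
        assert (m.states == m2.states).all()


def test_iter_call_records_reads_metrics(tmp_path):
    path = _vcf(tmp_path, "s1", [(42, "T", "C", 33, "0/1", 6, 5)])
    (rec,) = list(iter_call_records(path))
    assert (rec.chromosome, rec.position, rec.ref_allele, rec.alt_allele) == ("chr1", 42, "T", "C")
    assert rec.genotype == "het" and rec.depth == 11 and rec.alt_reads == 5
    assert rec.base_quality == 33.0
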