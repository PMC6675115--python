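"""SNV-call acceptance filtering and cross-sample genotype matrix assembly.

Per-sample VCFs are screened with the call-quality criteria (base
quality >= 20, read depth < 100, and for alt-bearing calls more than 3
alt-supporting reads) and merged into a site x sample grid of diploid
genotype states, the substrate of the family contrast.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from extremediff._util import chrom_sort_key
from extremediff.config import PipelineConfig

log = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

_STATE_CODE = {HOM_REF: 0, HET: 1, HOM_ALT: 2, MISSING: -1}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CallRecord:
    """One sample's call at one biallelic site, with its quality metrics."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    sample: str
    genotype: str  # hom_ref | het | hom_alt | missing
    base_quality: float
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"alleles must be single bases, got {self.ref_allele}/{self.alt_allele}")
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")
        if self.genotype not in _STATE_CODE:
            raise ValueError(f"unknown genotype state {self.genotype!r}")


def passes_call_filters(record: CallRecord, config: PipelineConfig | None = None) -> bool:
    """SNV-call acceptance: quality >= 20, depth < 100, alt reads > 3.

    The alt-read requirement applies to calls that assert the alternate
    allele (het / hom_alt); an explicit reference call carries no alt
    allele to support and is screened on quality and depth alone.
    Missing-genotype records never pass.
    """
    cfg = config or PipelineConfig()
    if record.genotype == MISSING:
        return False
    if record.base_quality < cfg.min_base_quality:
        return False
    if record.depth >= cfg.max_depth_exclusive:
        return False
    if record.genotype in (HET, HOM_ALT) and record.alt_reads <= cfg.min_alt_reads_exclusive:
        return False
    return True


@dataclass
class GenotypeMatrix:
    """Genotype states over the union of sites across samples.

    sites are (chromosome, position, ref, alt) tuples sorted by natural
    chromosome order then position; states is an int8 grid coded
    0=hom_ref, 1=het, 2=hom_alt, -1=missing.
    """

    sites: list  # [(chrom, pos, ref, alt)]
    samples: list
    states: np.ndarray  # shape (n_sites, n_samples)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sites), len(self.samples)):
            raise ValueError("states grid does not match sites x samples")

    def state(self, site_index: int, sample: str) -> str:
        return _CODE_STATE[int(self.states[site_index, self.samples.index(sample)])]

    def column(self, sample: str) -> np.ndarray:
        return self.states[:, self.samples.index(sample)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["chromosome", "position", "ref", "alt", *self.samples])
            for i, (chrom, pos, ref, alt) in enumerate(self.sites):
                writer.writerow(
                    [chrom, pos, ref, alt]
                    + [_CODE_STATE[int(c)] for c in self.states[i]]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            samples = header[4:]
            sites, rows = [], []
            for row in reader:
                sites.append((row[0], int(row[1]), row[2], row[3]))
                rows.append([_STATE_CODE[s] for s in row[4:]])
        return cls(sites, samples, np.array(rows, dtype=np.int8).reshape(len(sites), len(samples)))


def read_design(path: str | Path) -> list:
    """Read the family design CSV (family_id, high_sample, low_sample)."""
    families = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            families.append((row["family_id"], row["high_sample"], row["low_sample"]))
    if not families:
        raise ValueError(f"family design {path} is empty")
    return families


def _classify_gt(gt: tuple, alt_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    n_ref = sum(1 for a in gt if a == 0)
    if n_ref == len(gt):
        return HOM_REF
    if n_alt == len(gt):
        return HOM_ALT
    if n_alt > 0 and n_ref > 0:
        return HET
    return MISSING  # genotype references some other alt allele


def iter_call_records(vcf_path: str | Path, sample: str | None = None) -> Iterable[CallRecord]:
    """Yield CallRecords from a VCF, splitting multi-allelic rows per alt."""
    with pysam.VariantFile(str(vcf_path)) as vf:
        names = list(vf.header.samples)
        if sample is None:
            if len(names) != 1:
                raise ValueError(f"{vcf_path} has {len(names)} samples; specify one")
            sample = names[0]
        elif sample not in names:
            raise ValueError(f"sample {sample!r} not in {vcf_path}")
        for rec in vf:
            if rec.alts is None:
                continue
            call = rec.samples[sample]
            ad = call.get("AD")
            dp = call.get("DP")
            qual = rec.qual if rec.qual is not None else 0.0
            for ai, alt in enumerate(rec.alts, start=1):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in _BASES:
                    continue  # SNVs only
                state = _classify_gt(call.get("GT"), ai)
                alt_reads = int(ad[ai]) if ad is not None and len(ad) > ai and ad[ai] is not None else 0
                depth = int(dp) if dp is not None else (sum(x for x in ad if x is not None) if ad else 0)
                yield CallRecord(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    sample=sample,
                    genotype=state,
                    base_quality=float(qual),
                    depth=depth,
                    alt_reads=min(alt_reads, depth),
                )


def build_matrix(
    vcf_paths: Sequence[str | Path] | dict,
    design: Sequence[tuple],
    config: PipelineConfig | None = None,
) -> GenotypeMatrix:
    """Assemble the filtered genotype matrix over the union of sites.

    vcf_paths may be a mapping sample -> path or a sequence of
    single-sample VCF paths. Records failing the call filters are
    demoted to missing; a sample with no record at a union site is
    scored by config.absent_means (default missing). Positions with
    more than two observed alt alleles are dropped with a warning.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if isinstance(vcf_paths, dict):
        sample_paths = dict(vcf_paths)
    else:
        sample_paths = {}
        for p in vcf_paths:
            with pysam.VariantFile(str(p)) as vf:
                names = list(vf.header.samples)
            if len(names) != 1:
                raise ValueError(f"{p} must be single-sample (has {names})")
            sample_paths[names[0]] = p

    samples: list = []
    for _fam, high, low in design:
        samples.extend([high, low])
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be unique across the design")
    for s in samples:
        if s not in sample_paths:
            raise ValueError(f"design sample {s!r} has no VCF")

    # (chrom, pos) -> ref; (chrom, pos, alt) -> {sample: state}
    refs: dict = {}
    calls: dict = {}
    for s in samples:
        for rec in iter_call_records(sample_paths[s], sample=s):
            key = (rec.chromosome, rec.position)
            if key in refs and refs[key] != rec.ref_allele:
                raise ValueError(
                    f"conflicting ref alleles at {rec.chromosome}:{rec.position}: "
                    f"{refs[key]} vs {rec.ref_allele}"
                )
            refs[key] = rec.ref_allele
            state = rec.genotype if passes_call_filters(rec, cfg) else MISSING
            calls.setdefault(key, {}).setdefault(rec.alt_allele, {})[s] = state

    absent_code = _STATE_CODE[MISSING if cfg.absent_means == "missing" else HOM_REF]
    sites, rows = [], []
    for (chrom, pos), per_alt in calls.items():
        if len(per_alt) > 2:
            warnings.warn(
                f"dropping {chrom}:{pos}: {len(per_alt)} observed alt alleles",
                stacklevel=2,
            )
            continue
        for alt, per_sample in per_alt.items():
            sites.append((chrom, pos, refs[(chrom, pos)], alt))
            rows.append(
                [_STATE_CODE[per_sample[s]] if s in per_sample else absent_code for s in samples]
            )

    order = sorted(
        range(len(sites)), key=lambda i: (chrom_sort_key(sites[i][0]), sites[i][1], sites[i][3])
    )
    sites = [sites[i] for i in order]
    states = (
        np.array([rows[i] for i in order], dtype=np.int8).reshape(len(sites), len(samples))
        if sites
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    log.info("built genotype matrix: %d sites x %d samples", len(sites), len(samples))
    return GenotypeMatrix(sites, samples, states)
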