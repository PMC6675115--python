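"""Opposite-fixed site screening within and across sib families.

A site qualifies within a family when the high-group member is
homozygous for one allele and the low-group member is homozygous for a
different allele. The "common differential SNVs" are the sites where
every family qualifies with the same orientation (the same allele fixed
in every high sample and the same other allele fixed in every low
sample).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from extremediff.variant_filter import GenotypeMatrix, HET, HOM_ALT, HOM_REF

_CODE_HOM_REF = 0
_CODE_HET = 1
_CODE_HOM_ALT = 2


@dataclass(frozen=True)
class FamilyDesign:
    """families: list of (family_id, high_sample, low_sample)."""

    families: tuple

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("design must contain at least one family")
        samples = [s for _f, h, l in self.families for s in (h, l)]
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique across the design")

    @classmethod
    def from_rows(cls, rows: Sequence[tuple]) -> "FamilyDesign":
        return cls(tuple((f, h, l) for f, h, l in rows))

    def swapped(self) -> "FamilyDesign":
        """Exchange the high/low labels of every family."""
        return FamilyDesign(tuple((f, l, h) for f, h, l in self.families))


@dataclass(frozen=True)
class DifferentialSNV:
    chromosome: str
    position: int
    ref: str
    alt: str
    high_allele: str
    low_allele: str
    per_family_support: tuple

    def __post_init__(self) -> None:
        if self.high_allele == self.low_allele:
            raise ValueError("high and low alleles must differ")


def _alleles(ref: str, alt: str, state_code: int) -> str:
    return ref if state_code == _CODE_HOM_REF else alt


def family_differential(
    matrix: GenotypeMatrix,
    family: tuple,
    polymorphic_only: bool = False,
) -> list:
    """Sites where one family's high/low pair is fixed for opposite alleles.

    Returns [(site, high_allele, low_allele)]. With polymorphic_only the
    looser intermediate list is returned instead: every site where the
    two sibs differ (neither missing), with alleles set to None for
    non-fixed pairs.
    """
    _fam, high, low = family
    for s in (high, low):
        if s not in matrix.samples:
            raise ValueError(f"family sample {s!r} not in matrix")
    hc = matrix.column(high)
    lc = matrix.column(low)
    out = []
    for i, site in enumerate(matrix.sites):
        h, l = int(hc[i]), int(lc[i])
        if h < 0 or l < 0:
            continue
        fixed = h != l and h != _CODE_HET and l != _CODE_HET
        if fixed:
            ref, alt = site[2], site[3]
            out.append((site, _alleles(ref, alt, h), _alleles(ref, alt, l)))
        elif polymorphic_only and h != l:
            out.append((site, None, None))
    return out


def common_differential(matrix: GenotypeMatrix, design: FamilyDesign) -> list:
    """Sites opposite-fixed in every family with a consistent orientation.

    Equivalent to: all high samples homozygous for one allele A, all low
    samples homozygous for a different allele B. Output is a list of
    DifferentialSNV sorted by (chromosome, position) (matrix order).
    """
    if not design.families:
        raise ValueError("empty design")
    per_family = {}
    for fam in design.families:
        per_family[fam[0]] = {
            site: (ha, la) for site, ha, la in family_differential(matrix, fam)
        }
    family_ids = [f[0] for f in design.families]
    first = per_family[family_ids[0]]
    out = []
    for site, orientation in first.items():
        if all(per_family[fid].get(site) == orientation for fid in family_ids[1:]):
            out.append(
                DifferentialSNV(
                    chromosome=site[0],
                    position=site[1],
                    ref=site[2],
                    alt=site[3],
                    high_allele=orientation[0],
                    low_allele=orientation[1],
                    per_family_support=tuple(family_ids),
                )
            )
    index = {site: i for i, site in enumerate(matrix.sites)}
    out.sort(key=lambda d: index[(d.chromosome, d.position, d.ref, d.alt)])
    return out


def write_differential_tsv(diffs: Sequence[DifferentialSNV], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chromosome", "position", "ref", "alt", "high_allele", "low_allele"])
        for d in diffs:
            w.writerow([d.chromosome, d.position, d.ref, d.alt, d.high_allele, d.low_allele])


def read_differential_tsv(path: str | Path, families: Sequence[str] = ()) -> list:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                DifferentialSNV(
                    chromosome=row["chromosome"],
                    position=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    high_allele=row["high_allele"],
                    low_allele=row["low_allele"],
                    per_family_support=tuple(families),
                )
            )
    return out
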