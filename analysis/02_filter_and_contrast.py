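"""Filter the per-sample calls and screen for common differential SNVs.

Reads the simulated cohort from results/simulated/, applies the
call-quality filters (base quality >= 20, depth < 100, alt reads > 3),
assembles the genotype matrix over the union of sites, and keeps the
sites at which every family's high member is homozygous for one allele
and every low member homozygous for the other, with one consistent
orientation. Writes results/matrix.tsv and results/differential.tsv.
"""

import argparse
import sys
from pathlib import Path

from extremediff.family_contrast import FamilyDesign, common_differential, write_differential_tsv
from extremediff.variant_filter import build_matrix, read_design

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None) -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "simulated")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args(argv)

    design_rows = read_design(args.sim / "design.csv")
    vcfs = {s: args.sim / "vcf" / f"{s}.vcf" for _f, h, l in design_rows for s in (h, l)}
    matrix = build_matrix(vcfs, design_rows)
    args.out.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(args.out / "matrix.tsv")
    print(f"genotype matrix: {len(matrix.sites)} sites x {len(matrix.samples)} samples")

    diffs = common_differential(matrix, FamilyDesign.from_rows(design_rows))
    write_differential_tsv(diffs, args.out / "differential.tsv")
    print(f"common differential SNVs (opposite fixed across all 4 families): {len(diffs)}")


if __name__ == "__main__":
    sys.exit(main())
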