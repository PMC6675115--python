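"""Annotate the common differential SNVs against the gene models.

Assigns each SNV one of nine functional categories (coding effects for
exonic sites), prints the category summary, and attaches SNVs to genes
within the 5 kb window. Writes results/annotations.tsv and the two
category-summary tables.
"""

import argparse
import sys
from pathlib import Path

from pyfaidx import Fasta

from extremediff.annotator import (
    GeneIndex,
    annotate_sites,
    attach_to_genes,
    load_gene_models,
    summarize_categories,
    write_annotation_tsv,
)
from extremediff.family_contrast import read_differential_tsv

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None) -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "simulated")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args(argv)

    genes = load_gene_models(args.sim / "genes.gff3")
    index = GeneIndex(genes)
    reference = Fasta(str(args.sim / "reference.fa"))
    diffs = read_differential_tsv(args.out / "differential.tsv")
    sites = [(d.chromosome, d.position, d.ref, d.alt) for d in diffs]

    annotations = annotate_sites(sites, index, reference)
    write_annotation_tsv(annotations, args.out / "annotations.tsv")
    summary = summarize_categories(annotations)
    summary.to_tsv(args.out / "summary_differential.tsv")
    print(f"annotated {summary.total} differential SNVs:")
    for cat, count, pct in summary.to_rows():
        print(f"  {cat:<22s} {count:>6} {pct if pct != '' else '':>8}")

    assignments, retained = attach_to_genes(sites, annotations, index)
    attached = {site for site, *_r in assignments}
    if attached:
        near = summarize_categories([a for a in annotations if a.site in attached])
        near.to_tsv(args.out / "summary_near_gene.tsv")
    genes_hit = sorted({g for _s, _a, g, _d in assignments})
    (args.out / "query_genes.txt").write_text("".join(g + "\n" for g in genes_hit))
    print(f"{retained} SNVs within 5 kb of a gene -> {len(genes_hit)} genes for enrichment")


if __name__ == "__main__":
    sys.exit(main())
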