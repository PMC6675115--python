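# Methods

## The screen

The unit of evidence is the *opposite-fixed site*. For a biallelic SNV
with alleles {A, B} and four sib families each split into a high- and a
low-EBV member, the site is a **common differential SNV** when every
high sample is homozygous A and every low sample is homozygous B (or
vice versa), with one orientation shared by all families. Heterozygous
or missing genotypes disqualify a site: under a genotype-state model
{hom_ref, het, hom_alt, missing}, exactly two of the nine ordered
high/low state pairs qualify per family — the two opposite-homozygote
pairs — so the screen is equivalently "the intersection of per-family
opposite-fixation, filtered for orientation agreement". We require
orientation consistency across families (the stricter of the two
possible readings) because a single high/low allele per SNV is only
well-defined under it; the looser per-family reading is deliberately
not offered.

No significance is attached to fixation: with one diploid pair per
family the pattern is a filter, not a test. Selection statistics (FST,
XP-EHH, haplotype methods) are out of scope.

## Call acceptance

A call is accepted when base quality ≥ 20, read depth < 100
(strictly — depth 100 fails), and, *for calls asserting the alternate
allele* (het or hom_alt), more than 3 alt-supporting reads (i.e. ≥ 4).
The alt-read criterion is an SNV-call acceptance rule: an explicit
reference call (GT 0/0, zero alt reads by definition) asserts no
alternate allele and is screened on quality and depth only. Applying
the alt-read threshold to reference calls would make every opposite
hom_ref/hom_alt contrast undetectable, i.e. the screen would be
vacuous. Records failing acceptance are demoted to *missing*, never
silently re-scored.

Single-sample VCFs cannot distinguish "homozygous reference" from "no
data" at sites other samples report. The assembly policy
`absent_means` ∈ {missing (default), hom_ref} makes both readings
available; the simulator emits explicit 0/0 records so the default
conservative policy is exercised. Positions with more than two observed
alternate alleles across samples are dropped with a warning; two
observed alternates are split into two biallelic matrix sites. All
public coordinates are 1-based VCF/GFF3 conventions.

## Annotation

Categories are mutually exclusive with ANNOVAR-style precedence:
exonic (CDS) > 5'UTR > 3'UTR > intronic > ncRNA_exonic >
ncRNA_intronic > upstream/downstream > intergenic; among equal-priority
genes the nearest wins, ties broken by the smaller gene id. External
distances are to the nearer span boundary, min(|pos − start|,
|pos − end|). "Within 1 kb" and "within 5 kb" are boundary-inclusive
(≤ 1,000 / ≤ 5,000 bp); with 1-based inclusive spans this avoids
off-by-one ambiguity, and the worked upstream/downstream distances (81,
819, 683 bp) are consistent with either reading. Upstream/downstream is
strand-aware (upstream = 5′ of the transcription start);
"upstream;downstream" requires two distinct genes, one on each side.

Coding effects substitute the alt base into the spliced CDS in
transcript orientation (reverse-complemented on −), translate the
affected codon with the standard code, and compare: same residue →
synonymous; non-stop change → nonsynonymous; gain/loss of a stop →
stopgain/stoploss. A CDS whose length is not divisible by 3, or whose
reference base disagrees with the site's ref allele, yields *unknown*;
such sites are flagged, never dropped. Splice-site classes, indels and
multi-transcript consequence ranking are out of scope.

Category percentages are printed half-up to 2 decimals (so a table of
counts reproduces its printed percentages exactly; Python's default
banker's rounding would not).

## Enrichment

Over-representation only: p = P(X ≥ k) for X ~ Hypergeom(N, K, n),
computed by `scipy.stats.hypergeom.sf(k − 1, N, K, n)` (tests verify
agreement with exact rational enumeration to < 1e−9 for every margin
with N ≤ 25). The background is the full gene-model universe, not the
union of the gene sets. Raw P < 0.05 defines significance, matching the
screen's original convention; a Benjamini–Hochberg flag exists but
defaults off — the final candidate rule does not lean on the p-values
alone, and fidelity to the screen was preferred over correction.

Gene selection is the union of (a) query genes in significant sets
whose label matches a relevance keyword (defaults: "protein", "lipid",
"fatty acid"; case-insensitive substring), mechanizing what was
originally a manual curation, and (b) query genes in any of the eight
whitelisted pathways regardless of significance (the Methods-style
8-pathway list is the default; a 6-pathway variant exists in the
narrative of the source material and is reachable by configuration).

## QTL proximity

Physical positions map to cM by piecewise-linear interpolation between
per-chromosome (bp, cM) anchors, strictly increasing on both axes;
queries beyond the terminal anchors extrapolate with the terminal
segment's slope. The gene's cM position is taken at its span start
(the method behind published single-cM gene positions is unstated;
span start is deterministic and documented, midpoint is available via
`gene_cm_from="midpoint"`). A gene is retained when its *unrounded*
minimum distance to any peak of a PP/PY/FP/FY QTL is < 1.0 cM
(strict); distances are displayed half-up to 1 decimal. QTL records may
carry several peaks; the minimum over peaks is used. Only the peak rule
is implemented — confidence-interval overlap is mentioned in the source
material but never used by its filter, and is out of scope.

Final candidates additionally need ≥ 1 attached common differential
SNV in an exonic, UTR, upstream, downstream or upstream;downstream
category assigned to that same gene; intronic or intergenic support
alone does not qualify.

## The synthetic study

The simulator emulates the statistical structure the screen assumes,
not bovine genomics:

* **Genome** — 3 chromosomes × 1 Mb by default, i.i.d. uniform bases.
  60 gene models (10% ncRNA) placed non-overlapping with ≥ 12 kb
  span-to-span gaps, so every planted site has exactly one gene within
  the 1 kb and 5 kb windows and truth categories are unambiguous
  (overlapping-gene behaviour is tested separately with hand-built
  fixtures). Coding genes have 1–3 exons, 50–150 codons, explicit
  UTRs; the designed CDS (ATG + non-stop codons + stop) is written
  into the reference in strand orientation, so re-reading the emitted
  FASTA + GFF3 and translating reproduces a valid ORF.
* **Cohort** — 8 samples in 4 families. 50 planted opposite-fixed
  sites: one per planted candidate gene in a rotating
  exonic/UTR5/UTR3/upstream/downstream category, the rest intronic in
  non-candidate genes or deep intergenic (> 5 kb from any gene), so
  only planted candidate genes can satisfy the regulatory-support
  rule. 2,000 background sites get genotypes independent of the
  high/low labels (per-cell het probability 0.3, site-specific allele
  frequency U(0.1, 0.9)) and are re-drawn if they would mimic an
  opposite-fixed pattern, making the planted truth exact by
  construction. Per-call depth ~ Poisson(8.1) clipped to [5, 99]
  (matching a ~8× design), base quality ~ N(30, 3) clipped to [20,
  60]; a configurable fraction of calls (default 5%) deliberately
  violates one acceptance threshold, and cells go missing with default
  probability 2%. Metric distributions are stand-ins — the original
  study reports no per-site metric distributions — so passing tests
  demonstrate the pipeline's logic, not calibration to real data.
* **Resources** — a 5-anchor/chromosome genetic map at ~1 cM/Mb with
  per-segment jitter (real bovine maps average ≈ 1 cM/Mb; our
  chromosomes are simply short); one QTL per planted candidate gene
  with its peak 0.1–0.7 cM from the gene's start, plus per-chromosome
  decoy QTLs ≥ 3 cM from every gene; one keyword-labelled gene set and
  one whitelisted-pathway set containing all planted candidates plus
  fillers, and five decoy sets. With a ~25-gene query against a
  60-gene background the enriched set is not always significant at
  raw P < 0.05 — recovery of the planted candidates is guaranteed by
  the whitelist rescue, which is the rule the original screen relied
  on for exactly this situation.

All randomness derives from `SimConfig.seed` through
per-stage `numpy` generators seeded as `[seed, stage]`; identical
configs give byte-identical files.

What the simulation does *not* model: linkage disequilibrium, pedigree
structure within families, EBV architecture, mapping/calling error
beyond the three thresholds, indels/CNVs, overlapping genes,
alternative transcripts. Noiseless recovery (precision = recall = 1)
therefore validates the pipeline's correctness, not its power on real
resequencing data.

## Problem sizes and numerical notes

The default study (3 Mb genome, 2,050 sites × 8 samples) runs the full
pipeline in a few seconds; unit tests use a 0.8 Mb / ~310-site study.
The hypergeometric tail is exact to < 1e−12 in the tested range;
genetic-map interpolation is verified against the two-point line
equation to 1e−9. Ties in candidate ordering are broken by
(chromosome, gene start, gene id); all display rounding is half-up and
never feeds back into selection.

## Known discrepancies in the published tables

Carried as documentation, not reproduced: the near-gene summary prints
3'UTR at 0.11% and 5'UTR at 1.07% although its own counts (140 and 14
of 13,099) give 1.07% and 0.11% — the two figures are evidently
swapped, and the summary operation follows the counts. One candidate
gene row mixes chromosomes between its physical and genetic positions,
and another's printed peak distance is inconsistent with its own cM
values (0.7 vs 9.1); both rows are excluded from worked-example
checks. The raw differential count (57,451) exceeds the annotated count
(57,419) by 32 unannotatable sites; the pipeline reports both totals.
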