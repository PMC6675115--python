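"""Published summary tables of the motivating Holstein study.

The pipeline was designed around a whole-genome resequencing study of
eight Holstein bulls (four sib families, each with one extremely high
and one extremely low breeding-value member for milk protein/fat
percentage). The raw sequence data are not public, but the study's
printed summary tables are, and they serve here as worked examples and
regression anchors: per-bull sequencing/SNV summaries, the functional
category counts of the annotated SNV sets, the alleles of the candidate
SNVs in the high and low groups, and the gene-to-QTL-peak distances of
the final candidates.
"""

from __future__ import annotations

# per-bull sequencing summary: family, sample, raw reads, mapped reads,
# mapped %, uniquely mapped %, genome coverage %, depth (x), SNV count
SEQUENCING_SUMMARY = [
    ("full-sib1", "high1", 289_952_310, 261_783_075, 92.01, 82.90, 98.58, 8, 4_925_685),
    ("full-sib1", "low1", 286_870_238, 252_201_294, 90.24, 80.88, 98.55, 8, 4_636_009),
    ("full-sib2", "high2", 292_878_886, 257_840_281, 91.28, 82.97, 98.59, 8, 5_075_588),
    ("full-sib2", "low2", 272_948_496, 241_748_531, 91.48, 81.69, 98.52, 8, 4_166_954),
    ("half-sib1", "high3", 251_953_446, 218_677_291, 89.03, 81.15, 98.34, 7, 4_306_882),
    ("half-sib1", "low3", 337_815_303, 314_651_325, 96.73, 83.75, 98.40, 10, 5_403_284),
    ("half-sib2", "high4", 288_003_254, 253_311_627, 91.01, 82.45, 98.61, 8, 4_572_191),
    ("half-sib2", "low4", 283_359_516, 255_124_411, 91.89, 85.16, 98.57, 8, 3_399_107),
]

# functional category counts of all 10,945,507 annotated SNVs
ALL_SNV_CATEGORY_COUNTS = {
    "intergenic": 8_715_765,
    "upstream": 33_515,
    "downstream": 36_840,
    "upstream;downstream": 624,
    "UTR3": 22_495,
    "UTR5": 3_832,
    "ncRNA_exonic": 216,
    "ncRNA_intronic": 2_357,
    "intronic": 2_094_358,
}
ALL_SNV_EXONIC_EFFECT_COUNTS = {
    "nonsynonymous": 11_843,
    "synonymous": 19_617,
    "stopgain": 75,
    "stoploss": 5,
    "unknown": 3_965,
}

# functional category counts of the 57,419 annotated common differential SNVs
DIFFERENTIAL_CATEGORY_COUNTS = {
    "intergenic": 45_188,
    "upstream": 161,
    "downstream": 193,
    "upstream;downstream": 4,
    "UTR3": 140,
    "UTR5": 14,
    "ncRNA_exonic": 2,
    "intronic": 11_541,
}
DIFFERENTIAL_EXONIC_EFFECT_COUNTS = {
    "nonsynonymous": 45,
    "synonymous": 116,
    "unknown": 15,
}

# the 13,099 common differential SNVs within 5 kb of a protein-coding gene
NEAR_GENE_CATEGORY_COUNTS = {
    "intergenic": 916,
    "upstream": 161,
    "downstream": 190,
    "upstream;downstream": 4,
    "UTR3": 140,
    "UTR5": 14,
    "intronic": 11_498,
}
NEAR_GENE_EXONIC_EFFECT_COUNTS = {
    "nonsynonymous": 45,
    "synonymous": 116,
    "unknown": 15,
}

#: raw and successfully annotated common-differential totals (32 sites
#: could not be annotated)
RAW_DIFFERENTIAL_TOTAL = 57_451
ANNOTATED_DIFFERENTIAL_TOTAL = 57_419

# candidate-SNV alleles: gene, gene start, gene end, chromosome, SNV
# category, SNV position, allele fixed in the high group, allele fixed
# in the low group
CANDIDATE_SNV_ALLELES = [
    ("ALG14", 48_600_669, 48_699_217, "1", "UTR5", 48_600_677, "T", "C"),
    ("ATP2C1", 140_368_052, 140_522_627, "1", "exonic", 140_375_966, "A", "G"),
    ("ATP2C1", 140_368_052, 140_522_627, "1", "exonic", 140_388_073, "A", "G"),
    ("PLD1", 96_517_508, 96_676_253, "1", "exonic", 96_594_836, "C", "T"),
    ("C3H1orf85", 14_558_546, 14_561_400, "3", "upstream", 14_558_465, "T", "C"),
    ("SNX7", 44_657_521, 44_775_833, "3", "downstream", 44_656_702, "A", "G"),
    ("MTHFD2L", 90_842_884, 90_986_715, "6", "downstream", 90_987_596, "A", "G"),
    ("CDKN2D", 16_298_106, 16_300_588, "7", "UTR3", 16_298_320, "G", "T"),
    ("COL5A3", 15_768_627, 15_813_561, "7", "exonic", 15_769_886, "G", "A"),
    ("FDX1L", 16_068_661, 16_073_072, "7", "UTR3", 16_068_671, "C", "G"),
    ("PIN1", 15_532_997, 15_545_250, "7", "UTR3", 15_544_947, "C", "T"),
    ("PIN1", 15_532_997, 15_545_250, "7", "UTR3", 15_544_948, "C", "T"),
    ("FIG4", 40_873_044, 41_046_003, "9", "exonic", 40_957_415, "G", "A"),
    ("EXOC7", 56_190_845, 56_208_380, "19", "exonic", 56_206_567, "G", "A"),
    ("LASP1", 40_090_994, 40_131_374, "19", "UTR3", 40_129_782, "C", "G"),
    ("LASP1", 40_090_994, 40_131_374, "19", "downstream", 40_131_920, "A", "G"),
    ("PGS1", 54_404_339, 54_441_590, "19", "downstream", 54_404_267, "T", "C"),
    ("SAO", 43_555_807, 43_559_785, "19", "downstream", 43_560_755, "A", "G"),
    ("SAO", 43_555_807, 43_559_785, "19", "downstream", 43_560_756, "A", "C"),
    ("GPLD1", 32_984_455, 33_036_038, "23", "upstream", 32_984_009, "C", "T"),
    ("MGEA5", 22_390_769, 22_417_775, "26", "upstream", 22_418_458, "A", "G"),
]

# candidate gene -> (gene cM position, QTL peak cM list, trait, printed
# distance).  Rows with internally inconsistent printed values (ALG14's
# chromosome mismatch; LASP1's printed 0.7 vs |51.3-60.4|) are omitted.
CANDIDATE_QTL_DISTANCES = [
    ("ATP2C1", 134.9, [134.64], "PP", 0.3),
    ("PLD1", 93.7, [93.5], "PY", 0.2),
    ("C3H1orf85", 24.3, [25.0], "FY,PP", 0.7),
    ("SNX7", 46.7, [45.95], "FY", 0.8),
    ("MTHFD2L", 100.0, [100.9], "PP", 0.9),
    ("MTHFD2L", 100.0, [100.38], "PP", 0.4),
    ("CDKN2D", 18.4, [17.8, 15.9], "PP", 0.6),
    ("COL5A3", 17.9, [17.8, 15.9], "PP", 0.1),
    ("FDX1L", 18.2, [15.9, 17.8], "PP", 0.4),
    ("PIN1", 17.5, [17.8, 15.9], "PP", 0.3),
    ("FIG4", 45.0, [44.4, 49.1], "FY,PY", 0.6),
    ("EXOC7", 96.1, [95.2], "PY", 0.9),
    ("PGS1", 93.1, [92.4], "FY", 0.7),
    ("SAO", 74.5, [75.0], "FP", 0.5),
    ("GPLD1", 44.2, [43.6], "FY", 0.6),
    ("MGEA5", 32.5, [31.72], "PP", 0.8),
]
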