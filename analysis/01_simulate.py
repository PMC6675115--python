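"""Generate the synthetic study cohort.

Emulates the study design the pipeline targets: eight bulls in four sib
families (one extreme-high, one extreme-low breeding-value member each),
~8x depth calls with quality metrics, 2,000 background SNVs, 50 planted
opposite-fixed sites and 5 planted candidate genes with matching gene
sets and QTL peaks. Writes everything under results/simulated/.
"""

import argparse
import sys
from pathlib import Path

from extremediff.config import SimConfig
from extremediff.simdata import TruthTable, simulate_study

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None) -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "simulated")
    args = ap.parse_args(argv)

    config = SimConfig(seed=args.seed)
    paths = simulate_study(config, args.out)
    truth = TruthTable.from_csv(paths["truth"])
    print(f"simulated study written to {args.out}")
    print(f"  {config.n_chromosomes} chromosomes x {config.chromosome_length_bp:,} bp, "
          f"{config.n_genes} genes")
    print(f"  8 samples, {config.n_background_snvs} background SNVs, "
          f"{len(truth.planted_sites)} planted differential sites")
    print(f"  planted candidate genes: {', '.join(truth.planted_candidate_genes)}")


if __name__ == "__main__":
    sys.exit(main())
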