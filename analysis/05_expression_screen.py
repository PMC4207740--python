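#!/usr/bin/env python
"""Day-night differential-expression screen and amplitude attenuation.

Runs the ZT16 vs ZT4 screen (empirical-Bayes moderated t, BH adjustment,
|FC| > 1.5 and adjusted p < 0.05) on the simulated expression matrix from
results/cohort/, for both genotypes, and compares pass lists and fold
changes between them.  The WT-like screen recovers the planted induced
transcripts; the mutant-like screen retains only the robust (clock-like)
subset, reproducing the attenuated day-night expression profile.
"""

import json
from pathlib import Path

import pandas as pd

from chronosleep import SimulationConfig
from chronosleep.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    config = SimulationConfig(random_seed=1)
    run_pipeline(config, stages=["screen"], out_dir=OUT)
    truth = json.loads((OUT / "expression_truth.json").read_text())
    planted = set(truth["planted_genes"])
    for genotype in ("WT", "MUT"):
        table = pd.read_csv(OUT / f"screen_{genotype}.csv", index_col="gene_id")
        passed = set(table.index[table["passed"]])
        print(
            f"{genotype}: {len(passed)} genes pass (|FC|>1.5, adj p<0.05); "
            f"{len(passed & planted)}/{len(planted)} planted recovered"
        )
    sets = json.loads((OUT / "pass_sets.json").read_text())
    print(
        f"pass-set split: WT-only {len(sets['wt_only'])}, shared {len(sets['shared'])}, "
        f"MUT-only {len(sets['mut_only'])}"
    )
    att = pd.read_csv(OUT / "attenuation.csv", index_col="gene_id")
    nonrobust = sorted(planted - set(truth["robust_genes"]))
    med = att.loc[nonrobust, "fc_ratio"].median()
    print(f"median mutant/WT linear FC ratio over non-robust planted genes: {med:.2f}")


if __name__ == "__main__":
    main()
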