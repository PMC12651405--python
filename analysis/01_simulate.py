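"""Stage 1: generate the synthetic NCII testcross trial.

Writes the genotype VCF, the plot-level phenotype table and the era labels
to results/analysis/inputs/, plus the true simulated effects for later
benchmarking of the estimators.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, RESULTS, SIM

from maizegca import simulate_genotypes, simulate_testcross_trial
from maizegca.io import write_fixtures


def main() -> None:
    genotypes, eras = simulate_genotypes(SIM)
    plots, truth = simulate_testcross_trial(SIM, genotypes)
    paths = write_fixtures(genotypes, eras, plots, INPUTS)

    truth_rows = []
    for trait, rec in truth.items():
        t = rec.true_gca_line.rename("true_gca").rename_axis("line_id").reset_index()
        t.insert(0, "trait", trait)
        truth_rows.append(t)
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.concat(truth_rows).to_csv(RESULTS / "true_gca_lines.csv", index=False)

    print(f"plots: {len(plots)} rows -> {paths['plots']}")
    print(f"VCF:   {genotypes.n_variants} variants x {genotypes.n_lines} lines -> {paths['vcf']}")
    print(f"eras:  {paths['eras']}")
    print(f"truth: {RESULTS / 'true_gca_lines.csv'}")


if __name__ == "__main__":
    main()
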