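"""Stage 2: multi-environment BLUP of hybrid values.

Fits the mixed model per trait (hybrid, hybrid x location and block-within-
location random; location fixed) and writes the 436 x traits BLUP table and
the REML variance components.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, RESULTS, TRAITS

from maizegca import blup_table, fit_multienv_blup, read_plot_table


def main() -> None:
    plots = read_plot_table(INPUTS / "plots.csv")
    results = {}
    for trait in TRAITS:
        results[trait] = fit_multienv_blup(plots, trait)
        vc = results[trait].variance_components
        print(f"{trait:5s} " + "  ".join(f"{k}={v:.3f}" for k, v in vc.items()))
    table = blup_table(results)
    table.to_csv(RESULTS / "blup_values.csv")
    pd.DataFrame({t: r.variance_components for t, r in results.items()}).T \
        .rename_axis("trait").to_csv(RESULTS / "blup_variance_components.csv")
    print(f"BLUP table {table.shape} -> {RESULTS / 'blup_values.csv'}")


if __name__ == "__main__":
    main()
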