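"""Stage 4: factorial ANOVA of the trial.

Per tester: the Blo x Loc x Cro joint table (three-way interaction as
error). Jointly: the combining-ability table with Line, Tester and their
location interactions. All tables are stacked into one CSV.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, RESULTS, TRAITS

from maizegca import joint_combining_anova, per_tester_anova, read_plot_table


def main() -> None:
    plots = read_plot_table(INPUTS / "plots.csv")
    frames = []
    for trait in TRAITS:
        for tester in sorted(plots["tester_id"].unique()):
            tab = per_tester_anova(plots, tester, trait)
            f = tab.to_frame()
            f.insert(0, "design", tab.design_name)
            f.insert(0, "trait", trait)
            frames.append(f)
        tab = joint_combining_anova(plots, trait)
        f = tab.to_frame()
        f.insert(0, "design", tab.design_name)
        f.insert(0, "trait", trait)
        frames.append(f)
        sig = f[f["sig"] != ""][["source", "p", "sig"]]
        print(f"{trait}: significant joint sources: "
              + (", ".join(f"{r.source} ({r.sig})" for r in sig.itertuples()) or "none"))
    out = pd.concat(frames)
    out.to_csv(RESULTS / "anova_tables.csv", index=False)
    print(f"-> {RESULTS / 'anova_tables.csv'}")


if __name__ == "__main__":
    main()
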