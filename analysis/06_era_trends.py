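"""Stage 6: breeding-era trends and elite-allele trajectories.

Tests per-era GCA differences (Welch) for every trait, computes the
cross-trait GCA correlation matrix, follows homozygote-class frequencies
of the top GWAS SNPs across eras and labels the favorable (elite) allele
per SNP, with figures for each step.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, PLOTS, RESULTS, TRAITS

from maizegca import (
    RunConfig,
    allele_trajectory,
    elite_allele_report,
    gca_correlation_matrix,
    gca_trend,
    load_vcf,
    qc_filter_variants,
    read_eras,
)
from maizegca.viz import correlation_heatmap, trajectory_plot, trend_plot

LOWER_IS_BETTER = RunConfig().lower_is_better


def main() -> None:
    eras = read_eras(INPUTS / "eras.csv")
    tidy = pd.read_csv(RESULTS / "combining_ability.csv")
    hits = pd.read_csv(RESULTS / "gwas_hits.csv")
    genotypes, _ = qc_filter_variants(load_vcf(INPUTS / "genotypes.vcf"))
    PLOTS.mkdir(parents=True, exist_ok=True)

    gca_by_trait = {}
    trend_frames, trajs = [], []
    for trait in TRAITS:
        rows = tidy[(tidy["trait"] == trait) & (tidy["effect_type"] == "gca_line")]
        gca = pd.Series(rows["value"].to_numpy(), index=rows["line_id"])
        gca_by_trait[trait] = gca
        rep = gca_trend(gca, eras, trait)
        f = rep.comparisons.copy()
        f.insert(0, "trait", trait)
        trend_frames.append(f)
        trend_plot(gca, eras, rep, PLOTS / f"trend_{trait}.png")
        stars = dict(zip(zip(f["era_a"], f["era_b"]), f["significance"]))
        print(f"{trait:5s} AGE1 vs AGE3: {stars[('AGE1', 'AGE3')]}")
        for sid in hits.loc[hits["trait"] == trait, "snp_id"].head(3):
            tr = allele_trajectory(genotypes, eras, sid, gca, trait=trait)
            trajs.append(tr)
            trajectory_plot(tr, PLOTS / f"trajectory_{trait}_{sid}.png")

    pd.concat(trend_frames).to_csv(RESULTS / "gca_trends.csv", index=False)
    r, _ = gca_correlation_matrix(pd.DataFrame(gca_by_trait))
    r.to_csv(RESULTS / "gca_correlations.csv")
    correlation_heatmap(r, PLOTS / "gca_correlations.png")

    if trajs:
        per = pd.concat([t.per_era.assign(snp_id=t.snp_id, trait=t.trait)
                         for t in trajs])
        per.to_csv(RESULTS / "allele_trajectories.csv", index=False)
        elite = elite_allele_report(
            trajs, {t: (t not in LOWER_IS_BETTER) for t in TRAITS})
        elite.to_csv(RESULTS / "elite_alleles.csv", index=False)
        print(elite.head(10).to_string(index=False))
    print(f"-> {RESULTS / 'gca_trends.csv'}; figures in {PLOTS}")


if __name__ == "__main__":
    main()
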