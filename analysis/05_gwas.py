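"""Stage 5: variant QC and GCA-GWAS.

Filters the genotype panel (biallelic, missingness, minor-allele carriers,
heterozygosity, MAF), associates per-line GCA with SNP dosage using top-3
genotype PCs, writes the full association tables and hit lists, and draws
Manhattan/QQ plots for each trait.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS, PLOTS, RESULTS, TRAITS

from maizegca import load_vcf, qc_filter_variants, run_gwas, significant_hits
from maizegca.viz import manhattan_plot, qq_plot


def main() -> None:
    genotypes = load_vcf(INPUTS / "genotypes.vcf")
    filtered, removed = qc_filter_variants(genotypes)
    print(f"QC: removed {removed}; retained {filtered.n_variants} variants")

    tidy = pd.read_csv(RESULTS / "combining_ability.csv")
    PLOTS.mkdir(parents=True, exist_ok=True)
    tables, hits = [], []
    for trait in TRAITS:
        rows = tidy[(tidy["trait"] == trait) & (tidy["effect_type"] == "gca_line")]
        gca = pd.Series(rows["value"].to_numpy(), index=rows["line_id"])
        res = run_gwas(gca, filtered, n_pcs=3, trait=trait)
        t = res.table.copy()
        t.insert(0, "trait", trait)
        tables.append(t)
        h = significant_hits(res)
        hits.append(h)
        manhattan_plot(res, PLOTS / f"manhattan_{trait}.png")
        qq_plot(res, PLOTS / f"qq_{trait}.png")
        print(f"{trait:5s} {len(h)} hits at p < {res.threshold:g}")

    pd.concat(tables).to_csv(RESULTS / "gwas_full.csv", index=False)
    pd.concat(hits).to_csv(RESULTS / "gwas_hits.csv", index=False)
    print(f"-> {RESULTS / 'gwas_hits.csv'}; figures in {PLOTS}")


if __name__ == "__main__":
    main()
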