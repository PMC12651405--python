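"""End-to-end orchestration: simulate/ingest -> BLUP -> combining ability
-> ANOVA -> GWAS -> era trends, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .blup import blup_cross_means, blup_table, fit_multienv_blup
from .combining import estimate_combining_ability, combining_from_means, rank_by_gca
from .config import RunConfig
from .anova import joint_combining_anova, per_tester_anova
from .gwas import THRESHOLD_PRESETS, load_vcf, qc_filter_variants, run_gwas, significant_hits
from .io import read_eras, read_plot_table, write_fixtures
from .simulate import simulate_genotypes, simulate_testcross_trial
from .trends import allele_trajectory, elite_allele_report, gca_correlation_matrix, gca_trend

log = logging.getLogger("maizegca")

CAVEATS = [
    "GWAS engine is a single-marker linear model with PC covariates, not a "
    "multi-locus model-selection method; interpret hit lists accordingly.",
    "significance threshold default 3.5e-5; alternative readings available: "
    + ", ".join(f"{k}={v:.3g}" for k, v in THRESHOLD_PRESETS.items()),
    "combining-ability ANOVA treats blocks as a crossed factor and tests "
    "against the pooled residual by default.",
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "caveats": list(CAVEATS), "stages": [], "outputs": {},
                      "gca_scope": config.gca_scope}
    for c in CAVEATS:
        log.info("caveat: %s", c)

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            genotypes, eras = simulate_genotypes(sim)
            plots, _truth = simulate_testcross_trial(sim, genotypes)
            paths = write_fixtures(genotypes, eras, plots, out / "inputs")
            manifest["mode"] = "simulate"
            manifest["sim_config"] = {k: v for k, v in sim.__dict__.items()
                                      if k != "variance_components"}
            manifest["sim_config"]["variance_components"] = sim.variance_components.__dict__
        else:
            paths = {"plots": config.plots_csv, "vcf": config.vcf, "eras": config.eras_csv}
            plots = read_plot_table(paths["plots"])
            genotypes = load_vcf(paths["vcf"])
            eras = read_eras(paths["eras"])
            manifest["mode"] = "ingest"
        manifest["inputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                              for k, p in paths.items()}
        manifest["stages"].append(stage)

        traits = config.traits or [c for c in plots.columns
                                   if c not in ("line_id", "tester_id", "location", "block")]
        testers = sorted(plots["tester_id"].unique())

        stage = "blup"
        blups = {}
        for trait in traits:
            blups[trait] = fit_multienv_blup(plots, trait)
            log.info("BLUP %s: variance components %s", trait,
                     blups[trait].variance_components)
        btab = blup_table(blups)
        btab.to_csv(out / "blup_values.csv")
        pd.DataFrame({t: r.variance_components for t, r in blups.items()}).T \
            .to_csv(out / "blup_variance_components.csv")
        manifest["outputs"]["blup_values"] = str(out / "blup_values.csv")
        manifest["stages"].append(stage)

        stage = "combining"
        ca_results, tidy, rankings = {}, [], []
        for trait in traits:
            if config.gca_scope == "blup":
                res = combining_from_means(blup_cross_means(blups[trait]), trait)
            else:
                res = estimate_combining_ability(plots, trait, scope="pooled")
            ca_results[trait] = res
            tidy.append(res.to_tidy())
            direction = "low" if trait in config.lower_is_better else "high"
            top = rank_by_gca(res, min(10, len(res.gca_lines)), direction=direction)
            rankings.append(pd.DataFrame({"trait": trait, "rank": range(1, len(top) + 1),
                                          "line_id": top, "direction": direction}))
        pd.concat(tidy).to_csv(out / "combining_ability.csv", index=False)
        pd.concat(rankings).to_csv(out / "gca_rankings.csv", index=False)
        manifest["outputs"]["combining_ability"] = str(out / "combining_ability.csv")
        manifest["stages"].append(stage)

        stage = "anova"
        anova_frames = []
        for trait in traits:
            for tester in testers:
                tab = per_tester_anova(plots, tester, trait)
                frame = tab.to_frame()
                frame.insert(0, "design", tab.design_name)
                frame.insert(0, "trait", trait)
                anova_frames.append(frame)
            tab = joint_combining_anova(plots, trait)
            frame = tab.to_frame()
            frame.insert(0, "design", tab.design_name)
            frame.insert(0, "trait", trait)
            anova_frames.append(frame)
        pd.concat(anova_frames).to_csv(out / "anova_tables.csv", index=False)
        manifest["outputs"]["anova_tables"] = str(out / "anova_tables.csv")
        manifest["stages"].append(stage)

        stage = "gwas"
        filtered, removed = qc_filter_variants(genotypes)
        manifest["qc_removed"] = removed
        manifest["qc_retained"] = int(filtered.n_variants)
        gwas_results, hit_frames = {}, []
        for trait in traits:
            res = run_gwas(ca_results[trait].gca_lines, filtered,
                           n_pcs=config.gwas_n_pcs, trait=trait,
                           threshold=config.gwas_threshold)
            gwas_results[trait] = res
            hit_frames.append(significant_hits(res))
        hits = pd.concat(hit_frames).reset_index(drop=True)
        hits.to_csv(out / "gwas_hits.csv", index=False)
        manifest["outputs"]["gwas_hits"] = str(out / "gwas_hits.csv")
        manifest["n_gwas_hits"] = int(len(hits))
        manifest["gwas_input"] = f"{config.gca_scope}-scope line GCA"
        manifest["stages"].append(stage)

        stage = "trends"
        trend_frames, traj_objs = [], []
        for trait in traits:
            rep = gca_trend(ca_results[trait].gca_lines, eras, trait, test=config.trend_test)
            f = rep.comparisons.copy()
            f.insert(0, "trait", trait)
            trend_frames.append(f)
            trait_hits = hits[hits["trait"] == trait]
            snp_ids = list(trait_hits["snp_id"][:3])
            if not snp_ids and len(gwas_results[trait].table):
                snp_ids = [gwas_results[trait].table.nsmallest(1, "p")["snp_id"].iloc[0]]
            for sid in snp_ids:
                traj_objs.append(allele_trajectory(filtered, eras, sid,
                                                   ca_results[trait].gca_lines,
                                                   trait=trait, test=config.trend_test))
        pd.concat(trend_frames).to_csv(out / "gca_trends.csv", index=False)
        gca_matrix = pd.DataFrame({t: ca_results[t].gca_lines for t in traits})
        r, p = gca_correlation_matrix(gca_matrix)
        r.to_csv(out / "gca_correlations.csv")
        traj_rows = []
        for tr in traj_objs:
            f = tr.per_era.copy()
            f.insert(0, "trait", tr.trait)
            f.insert(0, "snp_id", tr.snp_id)
            traj_rows.append(f)
        if traj_rows:
            pd.concat(traj_rows).to_csv(out / "allele_trajectories.csv", index=False)
        elite = elite_allele_report(
            traj_objs, {t: (t not in config.lower_is_better) for t in traits})
        elite.to_csv(out / "elite_alleles.csv", index=False)
        manifest["outputs"]["gca_trends"] = str(out / "gca_trends.csv")
        manifest["outputs"]["gca_correlations"] = str(out / "gca_correlations.csv")
        manifest["outputs"]["elite_alleles"] = str(out / "elite_alleles.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
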