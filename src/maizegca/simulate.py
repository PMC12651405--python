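"""Synthetic NCII testcross trial generator.

Emulates the structure of the study panel: inbred lines grouped into three
breeding eras (AGE1/AGE2/AGE3), crossed to a small tester set, phenotyped
in a replicated multi-location block design. Causal minor-allele
frequencies shift linearly across eras so that downstream era-trend and
allele-trajectory analyses have a known signal to recover; true line GCA
is the causal-dosage score topped up with a polygenic deviate so the
line-GCA variance stays a single interpretable knob.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ERAS, SimConfig
from .containers import GenotypeMatrix, InputError, TruthRecord

_BASES = ("A", "C", "G", "T")


def _era_frequency(base: float, shift: float, era_index: int) -> float:
    """Causal minor-allele frequency in era ``era_index`` (0-based).

    Shifted frequencies are clamped to [0.01, 0.99]; a frequency that comes
    out exactly 0 or 1 (an allele deliberately absent/fixed in an era) is
    preserved as-is.
    """
    f = base + era_index * shift
    if f == 0.0 or f == 1.0:
        return f
    return float(min(max(f, 0.01), 0.99))


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw an inbred-panel dosage matrix and per-line era labels.

    Lines are assigned to eras independently with ``era_proportions``.
    Every SNP is biallelic; causal SNPs (``n_causal_per_trait`` per trait,
    non-overlapping) have era-dependent alternate-allele frequencies
    ``base + k * era_freq_shift`` in era k; neutral SNPs share one frequency
    across eras. Heterozygous and missing calls are injected uniformly at
    random at ``het_rate`` / ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    line_ids = config.line_ids
    era_idx = rng.choice(3, size=config.n_lines, p=np.asarray(config.era_proportions))
    eras = pd.Series([ERAS[k] for k in era_idx], index=line_ids, name="era")

    n_snps = config.n_snps
    chrom = (np.arange(n_snps) % 10) + 1
    pos = (np.arange(n_snps) // 10 + 1) * 1000 + rng.integers(0, 1000, size=n_snps)
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4

    causal_trait = np.full(n_snps, "", dtype=object)
    causal_cols = rng.choice(n_snps, size=config.n_causal_per_trait * len(config.traits),
                             replace=False)
    for t_i, trait in enumerate(config.traits):
        cols = causal_cols[t_i * config.n_causal_per_trait:(t_i + 1) * config.n_causal_per_trait]
        causal_trait[cols] = trait

    # per-line, per-SNP alternate-allele frequency
    neutral_freq = rng.uniform(0.05, 0.5, size=n_snps)
    freq = np.tile(neutral_freq, (config.n_lines, 1))
    for col in causal_cols:
        for k in range(3):
            f_k = _era_frequency(config.causal_base_freq, config.era_freq_shift, k)
            freq[era_idx == k, col] = f_k

    # fully inbred draw, then het / missing injection
    dosages = np.where(rng.random((config.n_lines, n_snps)) < freq, 2.0, 0.0)
    if config.het_rate > 0:
        dosages[rng.random(dosages.shape) < config.het_rate] = 1.0
    if config.missing_rate > 0:
        dosages[rng.random(dosages.shape) < config.missing_rate] = np.nan

    variants = pd.DataFrame(
        {
            "snp_id": [f"S{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": [_BASES[i] for i in ref_i],
            "alt": [_BASES[i] for i in alt_i],
            "n_alleles": 2,
            "causal_trait": causal_trait,
        }
    )
    return GenotypeMatrix(dosages, list(line_ids), variants), eras


def _double_center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def simulate_testcross_trial(
    config: SimConfig, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, dict[str, TruthRecord]]:
    """Draw plot-level phenotypes for every line x tester x location x block.

    Plot value = grand mean + location + block(location) + line GCA
    + tester GCA + SCA + line x location deviate + residual. True line GCA
    is the centered causal-dosage score; if the markers explain less than
    ``var_gca_line`` the remainder is added as an independent polygenic
    normal deviate, if more, the score is rescaled.
    """
    config.validate()
    if genotypes.n_lines != config.n_lines:
        raise InputError(
            f"genotype panel has {genotypes.n_lines} lines, config expects {config.n_lines}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    line_ids = config.line_ids
    tester_ids = config.tester_ids
    loc_ids = config.location_ids
    blocks = [f"B{b + 1}" for b in range(config.n_blocks_per_location)]
    vc = config.variance_components

    f, m, L, B = config.n_lines, config.n_testers, config.n_locations, config.n_blocks_per_location

    index = pd.MultiIndex.from_product(
        [line_ids, tester_ids, loc_ids, blocks],
        names=["line_id", "tester_id", "location", "block"],
    )
    plots = index.to_frame(index=False)

    # broadcast helpers: plot order is line (slowest) x tester x loc x block
    def per_line(v):
        return np.repeat(v, m * L * B)

    def per_tester(v):
        return np.tile(np.repeat(v, L * B), f)

    def per_cross(mat):
        return np.repeat(mat.reshape(-1), L * B)

    def per_loc(v):
        return np.tile(np.repeat(v, B), f * m)

    def per_loc_block(mat):
        return np.tile(mat.reshape(-1), f * m)

    def per_line_loc(mat):
        return np.tile(np.repeat(mat, B, axis=1), m).reshape(f, m * L * B).reshape(-1)

    truth: dict[str, TruthRecord] = {}
    for trait in config.traits:
        causal_mask = genotypes.variants["causal_trait"].to_numpy() == trait
        causal_ids = genotypes.variants.loc[causal_mask, "snp_id"].tolist()
        dos = genotypes.dosages[:, causal_mask]
        # column-mean imputation of missing calls for the truth score only
        if np.isnan(dos).any():
            col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            dos = np.where(np.isnan(dos), col_mean, dos)
        effects = rng.normal(0.0, config.marker_effect_scale, size=dos.shape[1]) \
            if config.marker_effect_scale > 0 else np.zeros(dos.shape[1])
        g = dos @ effects
        g = g - g.mean()
        var_marker = float(g.var())
        target = vc.var_gca_line
        if target == 0.0:
            g = np.zeros(f)
        elif var_marker > target:
            g = g * np.sqrt(target / var_marker)
        else:
            g = g + rng.normal(0.0, np.sqrt(target - var_marker), size=f)
            g = g - g.mean()

        gca_t = rng.normal(0.0, np.sqrt(vc.var_gca_tester), size=m) if vc.var_gca_tester > 0 \
            else np.zeros(m)
        gca_t = gca_t - gca_t.mean()
        sca = rng.normal(0.0, np.sqrt(vc.var_sca), size=(f, m)) if vc.var_sca > 0 \
            else np.zeros((f, m))
        sca = _double_center(sca)
        loc_eff = rng.normal(0.0, np.sqrt(vc.var_loc), size=L) if vc.var_loc > 0 else np.zeros(L)
        blk_eff = rng.normal(0.0, np.sqrt(vc.var_block_within_loc), size=(L, B)) \
            if vc.var_block_within_loc > 0 else np.zeros((L, B))
        lxl = rng.normal(0.0, np.sqrt(vc.var_line_x_loc), size=(f, L)) \
            if vc.var_line_x_loc > 0 else np.zeros((f, L))
        resid = rng.normal(0.0, np.sqrt(vc.var_residual), size=f * m * L * B) \
            if vc.var_residual > 0 else np.zeros(f * m * L * B)

        values = (
            config.grand_mean
            + per_line(g)
            + per_tester(gca_t)
            + per_cross(sca)
            + per_loc(loc_eff)
            + per_loc_block(blk_eff)
            + per_line_loc(lxl)
            + resid
        )
        plots[trait] = values
        truth[trait] = TruthRecord(
            trait=trait,
            true_gca_line=pd.Series(g, index=line_ids),
            true_gca_tester=pd.Series(gca_t, index=tester_ids),
            true_sca=pd.DataFrame(sca, index=line_ids, columns=tester_ids),
            causal_snp_ids=causal_ids,
            causal_effects=effects,
            loc_effects=pd.Series(loc_eff, index=loc_ids),
            block_effects=pd.DataFrame(blk_eff, index=loc_ids, columns=blocks),
            line_x_loc=pd.DataFrame(lxl, index=line_ids, columns=loc_ids),
        )
    return plots, truth


def simulate_era_gca(
    era_means: tuple[float, float, float],
    sd: float,
    n_per_era: tuple[int, int, int] | int,
    seed: int,
) -> tuple[pd.Series, pd.Series]:
    """Draw per-line GCA values with era-specific means (trend calibration).

    Returns (gca values, era labels), both indexed by synthetic line ids.
    """
    if isinstance(n_per_era, int):
        n_per_era = (n_per_era,) * 3
    rng = np.random.default_rng(seed)
    ids, values, labels = [], [], []
    counter = 0
    for era, mean, n in zip(ERAS, era_means, n_per_era):
        for _ in range(n):
            counter += 1
            ids.append(f"L{counter:03d}")
            labels.append(era)
        values.extend(rng.normal(mean, sd, size=n))
    return (pd.Series(values, index=ids, name="gca"),
            pd.Series(labels, index=ids, name="era"))


def simulate_hybrid_trial(
    n_hybrids: int,
    n_env: int,
    n_reps: int,
    var_hybrid: float,
    var_hxe: float,
    var_exr: float,
    var_error: float,
    seed: int,
    grand_mean: float = 100.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw plot data straight from the multi-environment mixed model.

    Used for REML parameter-recovery checks: y = mu + Env + Hybrid
    + Hybrid x Env + Env x Rep + error, all random terms iid normal.
    Returns a long table (hybrid, env, rep, y) and the true hybrid effects.
    """
    rng = np.random.default_rng(seed)
    hybrids = [f"H{i + 1:04d}" for i in range(n_hybrids)]
    envs = [f"E{j + 1}" for j in range(n_env)]
    reps = [f"R{k + 1}" for k in range(n_reps)]
    env_eff = rng.normal(0.0, 1.0, size=n_env)  # fixed env differences, unit spread
    u_h = rng.normal(0.0, np.sqrt(var_hybrid), size=n_hybrids)
    u_hxe = rng.normal(0.0, np.sqrt(var_hxe), size=(n_hybrids, n_env)) if var_hxe > 0 \
        else np.zeros((n_hybrids, n_env))
    u_exr = rng.normal(0.0, np.sqrt(var_exr), size=(n_env, n_reps)) if var_exr > 0 \
        else np.zeros((n_env, n_reps))
    idx = pd.MultiIndex.from_product([hybrids, envs, reps], names=["hybrid", "env", "rep"])
    df = idx.to_frame(index=False)
    i = np.repeat(np.arange(n_hybrids), n_env * n_reps)
    j = np.tile(np.repeat(np.arange(n_env), n_reps), n_hybrids)
    k = np.tile(np.arange(n_reps), n_hybrids * n_env)
    df["y"] = (grand_mean + env_eff[j] + u_h[i] + u_hxe[i, j] + u_exr[j, k]
               + rng.normal(0.0, np.sqrt(var_error), size=len(df)))
    return df, pd.Series(u_h, index=hybrids, name="true_hybrid_effect")
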