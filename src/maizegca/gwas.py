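"""Variant QC and single-marker association on combining-ability values.

The association engine is a fixed-effect linear model per SNP — GCA
regressed on additive dosage (het = 1) with optional top principal
components of the genotype matrix as population-structure covariates.
This is a deliberately transparent substitute for multi-locus model-
selection GWAS methods; it is exact, deterministic and easy to calibrate.

QC retains variants that are biallelic, have missing rate < 0.2, carry the
minor allele in at least 5 lines, have heterozygosity rate < 0.1, and have
minor allele frequency > 0.05 (variants at MAF <= 0.05 are removed);
counts of removals are reported per criterion in application order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, InputError
from .io import load_vcf  # noqa: F401  (re-exported: VCF ingest lives with GWAS)

QC_MISSING_MAX = 0.2
QC_MIN_MINOR_CARRIERS = 5
QC_HET_MAX = 0.1
QC_MAF_MIN = 0.05  # exclusive: keep MAF > 0.05

#: the default screening threshold, the -log10 p > 6 reading, and a
#: genome-wide Bonferroni at the full SNP count of a resequencing panel
THRESHOLD_PRESETS = {
    "default": 3.5e-5,
    "log10_6": 1e-6,
    "bonferroni_full_panel": 0.05 / 15_232_270,
}


def variant_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, missing rate, het rate and minor-allele carriers,
    all computed over non-missing calls."""
    d = genotypes.dosages
    n_lines = d.shape[0]
    missing = np.isnan(d)
    n_called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(n_called > 0, np.nansum(d, axis=0) / (2 * n_called), np.nan)
        maf = np.minimum(alt_freq, 1 - alt_freq)
        het_rate = np.where(n_called > 0, (d == 1).sum(axis=0) / n_called, np.nan)
    alt_minor = alt_freq <= 0.5
    carries_alt = (d >= 1)
    carries_ref = (d <= 1)
    minor_carriers = np.where(alt_minor,
                              np.nansum(np.where(missing, 0, carries_alt), axis=0),
                              np.nansum(np.where(missing, 0, carries_ref), axis=0))
    out = genotypes.variants.copy()
    out["maf"] = maf
    out["missing_rate"] = missing.sum(axis=0) / n_lines
    out["het_rate"] = het_rate
    out["minor_allele_individuals"] = minor_carriers.astype(int)
    return out


def qc_filter_variants(
    genotypes: GenotypeMatrix,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the five variant filters sequentially; return the retained
    panel and per-criterion removal counts (in application order)."""
    stats_df = variant_stats(genotypes)
    keep = np.ones(genotypes.n_variants, dtype=bool)
    removed: dict[str, int] = {}

    def apply(name: str, passes: np.ndarray) -> None:
        fails = keep & ~passes
        removed[name] = int(fails.sum())
        keep[fails] = False

    n_alleles = stats_df["n_alleles"].to_numpy() if "n_alleles" in stats_df else np.full(
        genotypes.n_variants, 2)
    apply("biallelic", n_alleles == 2)
    apply("missing_rate", stats_df["missing_rate"].to_numpy() < QC_MISSING_MAX)
    apply("minor_allele_individuals",
          stats_df["minor_allele_individuals"].to_numpy() >= QC_MIN_MINOR_CARRIERS)
    apply("het_rate", stats_df["het_rate"].to_numpy() < QC_HET_MAX)
    apply("maf", stats_df["maf"].to_numpy() > QC_MAF_MIN)

    filtered = GenotypeMatrix(
        genotypes.dosages[:, keep],
        genotypes.line_ids,
        stats_df.loc[keep].reset_index(drop=True),
    )
    return filtered, removed


def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Top principal components of the (mean-imputed, centered) dosages."""
    if n_pcs == 0:
        return np.zeros((genotypes.n_lines, 0))
    d = genotypes.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    d -= d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    k = min(n_pcs, (s > 1e-10).sum())
    pcs = u[:, :k] * s[:k]
    if k < n_pcs:
        pcs = np.column_stack([pcs, np.zeros((genotypes.n_lines, n_pcs - k))])
    return pcs


@dataclass
class GwasResult:
    trait: str
    threshold: float
    table: pd.DataFrame      # snp_id, chrom, pos, beta, se, t, p, maf, n_used, degenerate
    n_lines_used: int = 0
    n_pcs: int = 0
    caveats: list[str] = field(default_factory=list)

    @property
    def hits(self) -> pd.DataFrame:
        return significant_hits(self, self.threshold)


def _ols_single(y: np.ndarray, x: np.ndarray, covars: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on [1, covars, x]; returns (beta_x, se, t, p)."""
    n = len(y)
    design = np.column_stack([np.ones(n), covars, x])
    p = design.shape[1]
    if n <= p:
        return 0.0, np.nan, 0.0, 1.0
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        return 0.0, np.nan, 0.0, 1.0
    resid = y - design @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    if se == 0.0:
        # perfect fit: effectively infinite evidence
        return float(coef[-1]), 0.0, np.inf, np.nextafter(0, 1)
    t = float(coef[-1]) / se
    return float(coef[-1]), se, t, float(2 * stats.t.sf(abs(t), dof))


def run_gwas(
    gca: pd.Series,
    genotypes: GenotypeMatrix,
    n_pcs: int = 3,
    trait: str = "GCA",
    threshold: float = THRESHOLD_PRESETS["default"],
) -> GwasResult:
    """Per-SNP linear-model association of per-line GCA with dosage.

    Lines missing a genotype are dropped for that variant only; a variant
    with no dosage variance after dropping gets p = 1, beta = 0 and a
    ``degenerate`` flag. P-values are invariant to affine rescaling of the
    GCA values.
    """
    common = [l for l in genotypes.line_ids if l in gca.index]
    if len(common) < 3 + n_pcs:
        raise InputError("too few lines shared between GCA values and genotypes")
    caveats = []
    if len(common) < genotypes.n_lines:
        caveats.append(
            f"{genotypes.n_lines - len(common)} genotyped lines lack GCA values; dropped")
    row_idx = [genotypes.line_ids.index(l) for l in common]
    d = genotypes.dosages[row_idx, :]
    y = gca.loc[common].to_numpy(dtype=float)
    sub = GenotypeMatrix(d, common, genotypes.variants)
    pcs = genotype_pcs(sub, n_pcs)
    stats_df = variant_stats(sub)

    n, m = d.shape
    any_missing = np.isnan(d).any()
    if np.var(y) == 0:
        # no GCA variation: nothing to associate
        table = pd.DataFrame({
            "snp_id": stats_df["snp_id"], "chrom": stats_df["chrom"],
            "pos": stats_df["pos"], "beta": 0.0, "se": np.nan, "t": 0.0,
            "p": 1.0, "maf": stats_df["maf"], "n_used": n, "degenerate": False,
        })
        return GwasResult(trait=trait, threshold=threshold, table=table,
                          n_lines_used=n, n_pcs=n_pcs,
                          caveats=caveats + ["constant GCA input"])
    betas = np.zeros(m)
    ses = np.full(m, np.nan)
    ts = np.zeros(m)
    ps = np.ones(m)
    ns = np.full(m, n, dtype=int)
    degenerate = np.zeros(m, dtype=bool)

    if not any_missing:
        # vectorized path: residualize y and all dosages on [1, PCs], then
        # per-variant simple regression on the residuals (same t as full OLS)
        C = np.column_stack([np.ones(n), pcs])
        Q, _ = np.linalg.qr(C)
        ry = y - Q @ (Q.T @ y)
        rd = d - Q @ (Q.T @ d)
        dof = n - C.shape[1] - 1
        sxx = (rd ** 2).sum(axis=0)
        degenerate = sxx <= 1e-12 * n
        sxy = rd.T @ ry
        ok = ~degenerate
        betas[ok] = sxy[ok] / sxx[ok]
        rss = (ry @ ry) - betas * sxy
        sigma2 = np.maximum(rss, 0.0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            ses[ok] = np.sqrt(sigma2[ok] / sxx[ok])
            exact = ok & (ses <= 0)
            ts[ok] = np.where(ses[ok] > 0, betas[ok] / ses[ok], np.inf)
        ps[ok] = 2 * stats.t.sf(np.abs(ts[ok]), dof)
        ps[exact] = np.nextafter(0, 1)
    else:
        for j in range(m):
            x = d[:, j]
            mask = ~np.isnan(x)
            ns[j] = int(mask.sum())
            xj, yj, cj = x[mask], y[mask], pcs[mask]
            if ns[j] < 3 + n_pcs or np.nanvar(xj) <= 1e-12:
                degenerate[j] = True
                continue
            betas[j], ses[j], ts[j], ps[j] = _ols_single(yj, xj, cj)

    ps = np.clip(ps, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame({
        "snp_id": stats_df["snp_id"],
        "chrom": stats_df["chrom"],
        "pos": stats_df["pos"],
        "beta": betas,
        "se": ses,
        "t": ts,
        "p": ps,
        "maf": stats_df["maf"],
        "n_used": ns,
        "degenerate": degenerate,
    })
    return GwasResult(trait=trait, threshold=threshold, table=table,
                      n_lines_used=len(common), n_pcs=n_pcs, caveats=caveats)


def significant_hits(result: GwasResult, threshold: float | None = None) -> pd.DataFrame:
    """Variants below the significance threshold, sorted by (chrom, pos),
    with columns mirroring the reporting convention
    (trait, SNP id, chromosome, position, p, MAF)."""
    thr = result.threshold if threshold is None else threshold
    if not (0 < thr <= 1):
        raise InputError("threshold must be in (0, 1]")
    hits = result.table[(result.table["p"] < thr) & (~result.table["degenerate"])]
    hits = hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return pd.DataFrame({
        "trait": result.trait,
        "snp_id": hits["snp_id"],
        "chrom": hits["chrom"],
        "pos": hits["pos"],
        "p": hits["p"],
        "maf": hits["maf"],
    })
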