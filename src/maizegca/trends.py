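"""Breeding-era trends in combining ability and elite-allele trajectories.

Lines are grouped into three release-era cohorts (AGE1 < AGE2 < AGE3).
`gca_trend` summarizes per-era GCA and tests consecutive-era pairs plus
AGE1 vs AGE3 (Welch's t by default — era cohorts differ in size and
spread — with a Mann-Whitney option). `allele_trajectory` follows the two
homozygote classes of a SNP across eras (heterozygous/missing calls are
excluded, the inbred-line convention) together with per-class GCA, and
`elite_allele_report` labels the favorable homozygote class per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ERAS
from .containers import GenotypeMatrix, InputError

_PAIRS = (("AGE1", "AGE2"), ("AGE2", "AGE3"), ("AGE1", "AGE3"))


def _stars(p: float | None) -> str:
    if p is None or np.isnan(p):
        return "na"
    return "**" if p < 0.01 else ("*" if p < 0.05 else "ns")


def _pair_test(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0  # identical distributions: no difference
        return np.inf, 0.0
    if test == "welch":
        r = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise InputError("test must be 'welch' or 'mannwhitney'")
    return float(r.statistic), float(r.pvalue)


@dataclass
class TrendReport:
    trait: str
    test: str
    per_era: pd.DataFrame       # era, n, mean, sd
    comparisons: pd.DataFrame   # era_a, era_b, statistic, p, significance

    def mean(self, era: str) -> float:
        return float(self.per_era.set_index("era").loc[era, "mean"])


def gca_trend(
    gca: pd.Series, eras: pd.Series, trait: str, test: str = "welch"
) -> TrendReport:
    """Per-era GCA summaries plus pairwise era comparisons for one trait."""
    common = gca.index.intersection(eras.index)
    if len(common) == 0:
        raise InputError("no lines shared between GCA values and era labels")
    g = gca.loc[common].astype(float)
    e = eras.loc[common]
    groups = {era: g[e == era].to_numpy() for era in ERAS}

    per_era = pd.DataFrame([
        {"era": era, "n": len(v),
         "mean": float(np.mean(v)) if len(v) else np.nan,
         "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan}
        for era, v in groups.items()
    ])
    comps = []
    for a, b in _PAIRS:
        va, vb = groups[a], groups[b]
        if len(va) < 2 or len(vb) < 2:
            comps.append({"era_a": a, "era_b": b, "statistic": np.nan, "p": np.nan,
                          "significance": "na"})
            continue
        stat, p = _pair_test(va, vb, test)
        comps.append({"era_a": a, "era_b": b, "statistic": stat, "p": p,
                      "significance": _stars(p)})
    return TrendReport(trait=trait, test=test, per_era=per_era,
                       comparisons=pd.DataFrame(comps))


def gca_correlation_matrix(gca_by_trait: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation (and p-value) matrix of GCA across traits.

    Expects a lines x traits table; pairs are complete rows. Returns
    (r matrix, p matrix), both symmetric with unit / zero diagonals.
    """
    df = gca_by_trait.dropna()
    if len(df) < 3:
        raise InputError("need >= 3 lines with complete GCA values")
    traits = list(df.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rr, pp = stats.pearsonr(df.iloc[:, i], df.iloc[:, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (pd.DataFrame(r, index=traits, columns=traits),
            pd.DataFrame(p, index=traits, columns=traits))


@dataclass
class AlleleTrajectory:
    snp_id: str
    trait: str
    classes: tuple[str, str]          # e.g. ("T/T", "C/C") = (ref hom, alt hom)
    per_era: pd.DataFrame             # era, class, n, frequency, gca_mean, gca_sd
    class_comparisons: pd.DataFrame   # per era: class-vs-class GCA test
    excluded_calls: int = 0           # het or missing, left out
    not_computable: list[str] = field(default_factory=list)

    def frequency(self, era: str, cls: str) -> float:
        m = self.per_era[(self.per_era["era"] == era) & (self.per_era["class"] == cls)]
        return float(m["frequency"].iloc[0]) if len(m) else np.nan

    def absent_classes(self) -> list[tuple[str, str]]:
        out = self.per_era[(self.per_era["frequency"] == 0.0) & (self.per_era["era_n"] > 0)]
        return list(zip(out["era"], out["class"]))


def allele_trajectory(
    genotypes: GenotypeMatrix,
    eras: pd.Series,
    snp_id: str,
    gca: pd.Series,
    trait: str = "GCA",
    test: str = "welch",
) -> AlleleTrajectory:
    """Per-era homozygote-class frequencies and per-class GCA at one SNP."""
    dos = genotypes.column(snp_id)
    meta = genotypes.variants.set_index("snp_id").loc[snp_id]
    ref_cls = f"{meta['ref']}/{meta['ref']}"
    alt_cls = f"{meta['alt']}/{meta['alt']}"
    lines = pd.Index(genotypes.line_ids)
    common = lines.intersection(eras.index)
    if len(common) == 0:
        raise InputError("no lines shared between genotypes and era labels")

    d = pd.Series(dos, index=lines).loc[common]
    e = eras.loc[common]
    g = gca.reindex(common)
    hom = d.isin([0.0, 2.0])
    excluded = int((~hom).sum())

    rows, comps, not_comp = [], [], []
    for era in ERAS:
        in_era = e == era
        era_n_lines = int(in_era.sum())
        sel = in_era & hom
        n_incl = int(sel.sum())
        if era_n_lines > 0 and n_incl == 0:
            not_comp.append(era)
        class_values = {}
        for cls, dose in ((ref_cls, 0.0), (alt_cls, 2.0)):
            members = sel & (d == dose)
            vals = g[members].dropna().to_numpy()
            n_cls = int(members.sum())
            rows.append({
                "era": era, "class": cls, "n": n_cls,
                "era_n": era_n_lines, "included_n": n_incl,
                "frequency": n_cls / n_incl if n_incl else np.nan,
                "gca_mean": float(np.mean(vals)) if len(vals) else np.nan,
                "gca_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "absent": bool(n_incl > 0 and n_cls == 0),
            })
            class_values[cls] = vals
        stat, p = _pair_test(class_values[ref_cls], class_values[alt_cls], test)
        comps.append({"era": era, "class_a": ref_cls, "class_b": alt_cls,
                      "statistic": stat, "p": p, "significance": _stars(p)})
    return AlleleTrajectory(
        snp_id=snp_id, trait=trait, classes=(ref_cls, alt_cls),
        per_era=pd.DataFrame(rows), class_comparisons=pd.DataFrame(comps),
        excluded_calls=excluded, not_computable=not_comp)


def elite_allele_report(
    trajectories: list[AlleleTrajectory],
    higher_is_better: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Rank SNPs by the GCA advantage of their favorable homozygote class.

    The favorable class is the homozygote with the better mean GCA pooled
    over eras, in the trait's favorable direction (``higher_is_better``
    maps trait -> bool, default True). Ties are flagged and left unlabeled.
    The frequency change is the AGE3 - AGE1 favorable-class frequency.
    """
    higher_is_better = higher_is_better or {}
    rows = []
    for tr in trajectories:
        per = tr.per_era
        pooled = {}
        for cls in tr.classes:
            sub = per[per["class"] == cls]
            w = sub["n"].to_numpy(dtype=float)
            mvals = sub["gca_mean"].to_numpy(dtype=float)
            ok = (w > 0) & ~np.isnan(mvals)
            pooled[cls] = float((w[ok] * mvals[ok]).sum() / w[ok].sum()) if ok.any() else np.nan
        a, b = tr.classes
        direction = higher_is_better.get(tr.trait, True)
        if np.isnan(pooled[a]) or np.isnan(pooled[b]) or pooled[a] == pooled[b]:
            fav, adv, tie = "", np.nan, True
        else:
            better = a if (pooled[a] > pooled[b]) == direction else b
            fav, tie = better, False
            adv = abs(pooled[a] - pooled[b])
        if fav:
            f1 = tr.frequency("AGE1", fav)
            f3 = tr.frequency("AGE3", fav)
            dfreq = f3 - f1 if not (np.isnan(f1) or np.isnan(f3)) else np.nan
        else:
            dfreq = np.nan
        rows.append({"snp_id": tr.snp_id, "trait": tr.trait,
                     "favorable_class": fav, "tie": tie,
                     "gca_advantage": adv, "freq_change_age1_to_age3": dfreq})
    out = pd.DataFrame(rows)
    return out.sort_values("gca_advantage", ascending=False, na_position="last") \
        .reset_index(drop=True)
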