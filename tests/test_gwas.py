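"""Variant QC and single-marker association: filter semantics, exact small
examples, affine invariance and power on a simulated causal signal."""

import numpy as np
import pandas as pd
import pytest

from maizegca import (
    genotype_pcs,
    qc_filter_variants,
    run_gwas,
    significant_hits,
    variant_stats,
)
from maizegca.containers import GenotypeMatrix, InputError
from maizegca.gwas import THRESHOLD_PRESETS, _ols_single


def make_geno(dosages, line_ids=None, n_alleles=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    line_ids = line_ids or [f"L{i}" for i in range(n)]
    variants = pd.DataFrame({
        "snp_id": [f"S1_{j + 1}" for j in range(m)],
        "chrom": 1, "pos": np.arange(1, m + 1),
        "ref": "A", "alt": "T",
        "n_alleles": n_alleles if n_alleles is not None else [2] * m,
    })
    return GenotypeMatrix(d, line_ids, variants)


def test_variant_stats_bruteforce():
    d = np.array([[0, 2, 1, np.nan],
                  [2, 2, 1, 0],
                  [0, 2, 0, 0],
                  [2, 0, 0, 2]], dtype=float)
    s = variant_stats(make_geno(d))
    assert np.allclose(s["maf"], [0.5, 0.25, 0.25, 2 / 6])
    assert np.allclose(s["missing_rate"], [0, 0, 0, 0.25])
    assert np.allclose(s["het_rate"], [0, 0, 0.5, 0])
    assert s["minor_allele_individuals"].tolist() == [2, 1, 2, 1]


def violator_panel():
    """60-line panel with exactly one violator per QC criterion plus a
    monomorphic variant (caught by the carrier filter) and one clean SNP."""
    n = 60
    cols, n_alleles = [], []

    good = np.zeros(n); good[:18] = 2           # maf 0.3
    cols.append(good); n_alleles.append(2)

    triallelic = np.zeros(n); triallelic[:18] = 2
    cols.append(triallelic); n_alleles.append(3)

    missing = np.zeros(n); missing[:18] = 2; missing[-15:] = np.nan  # 25% missing
    cols.append(missing); n_alleles.append(2)

    rare = np.zeros(n); rare[:4] = 2            # 4 carriers < 5, maf 0.067
    cols.append(rare); n_alleles.append(2)

    hethy = np.zeros(n); hethy[:10] = 2; hethy[10:18] = 1  # het rate 0.133
    cols.append(hethy); n_alleles.append(2)

    lowmaf = np.zeros(n); lowmaf[:5] = 1        # 5 carriers, maf 0.0417, het 0.083
    cols.append(lowmaf); n_alleles.append(2)

    mono = np.zeros(n)                          # 0 carriers
    cols.append(mono); n_alleles.append(2)

    return make_geno(np.column_stack(cols), n_alleles=n_alleles)


def test_qc_removes_each_violator_for_its_own_reason():
    g = violator_panel()
    filtered, removed = qc_filter_variants(g)
    assert removed == {"biallelic": 1, "missing_rate": 1,
                       "minor_allele_individuals": 2, "het_rate": 1, "maf": 1}
    assert filtered.variants["snp_id"].tolist() == ["S1_1"]  # only the clean SNP


def test_qc_boundaries_are_strict():
    """MAF exactly 0.05 is removed; 5 carriers and het just under 0.1 pass."""
    n = 60
    at_maf = np.zeros(n); at_maf[:4] = 1; at_maf[4] = 2  # alt freq 6/120 = 0.05 exactly
    keeper = np.zeros(n); keeper[:5] = 1; keeper[5:12] = 2  # maf 0.158, het 0.083, 12 carriers
    g = make_geno(np.column_stack([at_maf, keeper]))
    filtered, removed = qc_filter_variants(g)
    assert removed["maf"] == 1
    assert filtered.n_variants == 1


def test_qc_idempotent(small_trial):
    _, genotypes, _, _, _ = small_trial
    once, _ = qc_filter_variants(genotypes)
    twice, removed = qc_filter_variants(once)
    assert all(v == 0 for v in removed.values())
    assert twice.equals(once)


def test_exact_fit_beta_one():
    """GCA identical to dosage, no covariates: beta = 1 and overwhelming
    evidence (p below any usable threshold; residual SS is at rounding)."""
    rng = np.random.default_rng(0)
    d = rng.binomial(1, 0.4, size=(30, 5)) * 2.0
    g = make_geno(d)
    y = pd.Series(d[:, 2], index=g.line_ids)
    res = run_gwas(y, g, n_pcs=0)
    row = res.table.set_index("snp_id").loc["S1_3"]
    assert row["beta"] == pytest.approx(1.0, abs=1e-10)
    assert row["p"] < 1e-100


def test_affine_invariance_of_pvalues():
    rng = np.random.default_rng(1)
    d = rng.binomial(1, 0.4, size=(50, 20)) * 2.0
    g = make_geno(d)
    y = pd.Series(rng.normal(size=50) + 0.5 * d[:, 0], index=g.line_ids)
    p1 = run_gwas(y, g, n_pcs=2).table["p"]
    p2 = run_gwas(3.7 * y - 11.0, g, n_pcs=2).table["p"]
    assert np.allclose(p1, p2, rtol=1e-9)


def test_constant_gca_gives_p_one():
    rng = np.random.default_rng(2)
    d = rng.binomial(1, 0.4, size=(20, 6)) * 2.0
    g = make_geno(d)
    y = pd.Series(5.0, index=g.line_ids)
    res = run_gwas(y, g, n_pcs=0)
    assert (res.table["p"] == 1.0).all()
    assert (res.table["beta"] == 0.0).all()
    assert "constant GCA input" in res.caveats


def test_monomorphic_snp_degenerate_and_excluded_from_hits():
    rng = np.random.default_rng(3)
    d = rng.binomial(1, 0.4, size=(25, 4)) * 2.0
    d[:, 1] = 2.0  # monomorphic
    g = make_geno(d)
    y = pd.Series(d[:, 0] + rng.normal(scale=0.01, size=25), index=g.line_ids)
    res = run_gwas(y, g, n_pcs=0, threshold=0.05)
    row = res.table.set_index("snp_id").loc["S1_2"]
    assert bool(row["degenerate"]) and row["p"] == 1.0
    assert "S1_2" not in set(res.hits["snp_id"])
    assert "S1_1" in set(res.hits["snp_id"])


def test_vectorized_matches_per_variant_ols():
    """The missing-data loop and the vectorized path compute the same tests."""
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.4, size=(60, 15)).astype(float)
    g = make_geno(d)
    y = pd.Series(rng.normal(size=60) + 0.4 * d[:, 3], index=g.line_ids)
    pcs = genotype_pcs(g, 2)
    res = run_gwas(y, g, n_pcs=2)
    for j in range(15):
        beta, se, t, p = _ols_single(y.to_numpy(), d[:, j], pcs)
        row = res.table.iloc[j]
        assert row["beta"] == pytest.approx(beta, rel=1e-8)
        assert row["p"] == pytest.approx(p, rel=1e-6)


def test_missing_calls_dropped_per_variant():
    rng = np.random.default_rng(5)
    d = rng.binomial(1, 0.4, size=(40, 6)) * 2.0
    d[0:3, 2] = np.nan
    g = make_geno(d)
    y = pd.Series(rng.normal(size=40), index=g.line_ids)
    res = run_gwas(y, g, n_pcs=1)
    assert res.table["n_used"].tolist() == [40, 40, 37, 40, 40, 40]


def test_significant_hits_sorted_and_threshold_checked():
    rng = np.random.default_rng(6)
    d = rng.binomial(1, 0.4, size=(50, 10)) * 2.0
    g = make_geno(d)
    g.variants.loc[:, "chrom"] = [2, 1, 1, 2, 1, 2, 1, 2, 1, 2]
    y = pd.Series(d.sum(axis=1) + rng.normal(scale=0.5, size=50), index=g.line_ids)
    res = run_gwas(y, g, n_pcs=0, threshold=1e-3)
    hits = res.hits
    assert (hits["p"] < 1e-3).all()
    key = list(zip(hits["chrom"], hits["pos"]))
    assert key == sorted(key)
    with pytest.raises(InputError, match="threshold"):
        significant_hits(res, threshold=0.0)


def test_threshold_presets():
    assert THRESHOLD_PRESETS["default"] == 3.5e-5
    assert THRESHOLD_PRESETS["log10_6"] == 1e-6
    assert THRESHOLD_PRESETS["bonferroni_full_panel"] == pytest.approx(0.05 / 15_232_270)


def test_too_few_shared_lines_rejected():
    d = np.zeros((4, 3)); d[:2] = 2
    g = make_geno(d)
    y = pd.Series([1.0, 2.0], index=["L0", "L1"])
    with pytest.raises(InputError, match="too few"):
        run_gwas(y, g, n_pcs=3)


def test_causal_snp_is_top_hit():
    """A strong causal SNP ranks first in >= 90 of 100 replicates."""
    wins = 0
    for rep in range(100):
        rng = np.random.default_rng(500 + rep)
        d = rng.binomial(1, 0.3, size=(80, 50)) * 2.0
        g = make_geno(d)
        y = pd.Series(1.0 * d[:, 7] + rng.normal(size=80), index=g.line_ids)
        res = run_gwas(y, g, n_pcs=2)
        wins += res.table.loc[res.table["p"].idxmin(), "snp_id"] == "S1_8"
    assert wins >= 90
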