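"""Generator behavior: determinism, design shapes, truth invariants,
era-structured allele frequencies and variance calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maizegca import (
    SimConfig,
    VarianceComponents,
    simulate_era_gca,
    simulate_genotypes,
    simulate_testcross_trial,
)
from maizegca.config import ConfigurationError


def test_same_seed_bit_identical(small_config):
    g1, e1 = simulate_genotypes(small_config)
    g2, e2 = simulate_genotypes(small_config)
    assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)
    assert (e1 == e2).all()
    p1, _ = simulate_testcross_trial(small_config, g1)
    p2, _ = simulate_testcross_trial(small_config, g2)
    pd.testing.assert_frame_equal(p1, p2)


def test_different_seed_differs(small_config):
    other = SimConfig(**{**small_config.__dict__, "seed": small_config.seed + 1})
    g1, _ = simulate_genotypes(small_config)
    g2, _ = simulate_genotypes(other)
    assert not np.array_equal(g1.dosages, g2.dosages, equal_nan=True)


def test_full_design_shape():
    """218 lines x 2 testers x 3 locations x 3 blocks -> 3924 plots, 436 crosses."""
    cfg = SimConfig(n_lines=218, n_snps=20, n_causal_per_trait=1, traits=("YPP",), seed=1)
    g, _ = simulate_genotypes(cfg)
    plots, _ = simulate_testcross_trial(cfg, g)
    assert len(plots) == 218 * 2 * 3 * 3 == 3924
    assert plots.groupby(["line_id", "tester_id"]).ngroups == 436


def test_truth_zero_sum(small_trial):
    _, _, _, _, truth = small_trial
    for t in truth.values():
        assert abs(t.true_gca_line.sum()) < 1e-9
        assert abs(t.true_gca_tester.sum()) < 1e-9
        assert np.allclose(t.true_sca.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(t.true_sca.sum(axis=1), 0, atol=1e-9)


def test_degenerate_variances_constant_plots():
    """All variance knobs at zero: every plot equals the grand mean exactly."""
    cfg = SimConfig(n_lines=6, n_snps=20, n_causal_per_trait=1, traits=("YPP",),
                    variance_components=VarianceComponents(0, 0, 0, 0, 0, 0, 0),
                    marker_effect_scale=0.0, grand_mean=42.0, seed=2)
    g, _ = simulate_genotypes(cfg)
    plots, truth = simulate_testcross_trial(cfg, g)
    assert (plots["YPP"] == 42.0).all()
    assert (truth["YPP"].true_gca_line == 0).all()


def test_causal_allele_absent_in_age1_then_rises():
    """Base frequency 0 with +0.15/era: absent in AGE1, ~0.15/0.30 later."""
    cfg = SimConfig(n_lines=218, n_snps=20, n_causal_per_trait=3, traits=("TBN",),
                    causal_base_freq=0.0, era_freq_shift=0.15,
                    het_rate=0.0, missing_rate=0.0, seed=5)
    g, eras = simulate_genotypes(cfg)
    causal = g.variants["causal_trait"] == "TBN"
    dos = g.dosages[:, causal.to_numpy()]
    for era, expected in (("AGE1", 0.0), ("AGE2", 0.15), ("AGE3", 0.30)):
        in_era = (eras == era).to_numpy()
        freq = dos[in_era].mean(axis=0) / 2
        n = int(in_era.sum())
        if expected == 0.0:
            assert (freq == 0.0).all()
        else:
            lo, hi = stats.binom.interval(0.999, n, expected)
            assert ((freq * n >= lo - 1e-9) & (freq * n <= hi + 1e-9)).all()


def test_no_shift_null_frequencies_homogeneous():
    """With era_freq_shift = 0 the per-era causal frequencies differ only by
    sampling noise: the across-era chi-square is non-significant at the 0.01
    level for at least 95% of SNPs over replicates."""
    n_sig = n_tot = 0
    for rep in range(200):
        cfg = SimConfig(n_lines=218, n_snps=4, n_causal_per_trait=2, traits=("YPP",),
                        era_freq_shift=0.0, het_rate=0.0, missing_rate=0.0,
                        causal_base_freq=0.3, seed=1000 + rep)
        g, eras = simulate_genotypes(cfg)
        causal = (g.variants["causal_trait"] == "YPP").to_numpy()
        dos = g.dosages[:, causal]
        era_codes = eras.map({"AGE1": 0, "AGE2": 1, "AGE3": 2}).to_numpy()
        for j in range(dos.shape[1]):
            table = np.zeros((3, 2))
            for k in range(3):
                d = dos[era_codes == k, j]
                table[k] = [(d == 2).sum(), (d == 0).sum()]
            if (table.sum(axis=1) > 0).all():
                _, p, _, _ = stats.chi2_contingency(table)
                n_tot += 1
                n_sig += p < 0.01
    assert n_tot > 300
    assert n_sig / n_tot <= 0.05


def test_sca_noise_floor_when_var_sca_zero():
    """var_sca = 0 and tiny residual: estimated SCA collapses toward zero."""
    from maizegca import estimate_combining_ability

    cfg = SimConfig(n_lines=20, n_snps=20, n_causal_per_trait=1, traits=("YPP",),
                    variance_components=VarianceComponents(
                        var_gca_line=4, var_gca_tester=1, var_sca=0.0,
                        var_loc=1, var_block_within_loc=0.5,
                        var_line_x_loc=0.0, var_residual=1e-6),
                    seed=9)
    g, _ = simulate_genotypes(cfg)
    plots, _ = simulate_testcross_trial(cfg, g)
    res = estimate_combining_ability(plots, "YPP")
    assert res.sca.abs().max().max() < 1e-2


def test_residual_variance_calibrated():
    """Plot residuals (after removing every true effect) have variance
    within 10% of the configured var_residual = 1 across replicates."""
    pooled = []
    for rep in range(200):
        cfg = SimConfig(n_lines=8, n_testers=2, n_locations=2, n_blocks_per_location=2,
                        n_snps=10, n_causal_per_trait=1, traits=("YPP",),
                        variance_components=VarianceComponents(
                            var_gca_line=4, var_gca_tester=1, var_sca=1, var_loc=2,
                            var_block_within_loc=1, var_line_x_loc=1, var_residual=1.0),
                        seed=2000 + rep)
        g, _ = simulate_genotypes(cfg)
        plots, truth = simulate_testcross_trial(cfg, g)
        t = truth["YPP"]
        expected = (
            cfg.grand_mean
            + plots["line_id"].map(t.true_gca_line).to_numpy()
            + plots["tester_id"].map(t.true_gca_tester).to_numpy()
            + np.array([t.true_sca.loc[i, j] for i, j in
                        zip(plots["line_id"], plots["tester_id"])])
            + plots["location"].map(t.loc_effects).to_numpy()
            + np.array([t.block_effects.loc[l, b] for l, b in
                        zip(plots["location"], plots["block"])])
            + np.array([t.line_x_loc.loc[i, l] for i, l in
                        zip(plots["line_id"], plots["location"])])
        )
        pooled.append(plots["YPP"].to_numpy() - expected)
    var = np.var(np.concatenate(pooled))
    assert 0.9 < var < 1.1


def test_era_gca_generator_means_and_labels():
    gca, eras = simulate_era_gca((2.51, 0.6, -1.28), sd=1.0, n_per_era=73, seed=3)
    assert len(gca) == 219
    assert eras.value_counts().to_dict() == {"AGE1": 73, "AGE2": 73, "AGE3": 73}
    for era, mu in zip(("AGE1", "AGE2", "AGE3"), (2.51, 0.6, -1.28)):
        sem = 1.0 / np.sqrt(73)
        assert abs(gca[eras == era].mean() - mu) < 4 * sem


@pytest.mark.parametrize("field,value,fragment", [
    ("n_lines", 0, "n_lines"),
    ("era_proportions", (0.5, 0.5, 0.5), "era_proportions"),
    ("missing_rate", 0.5, "missing_rate"),
    ("het_rate", 0.2, "het_rate"),
])
def test_invalid_config_names_field(field, value, fragment):
    cfg = SimConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=fragment):
        cfg.validate()


def test_negative_variance_rejected():
    cfg = SimConfig(variance_components=VarianceComponents(var_sca=-1.0))
    with pytest.raises(ConfigurationError, match="var_sca"):
        cfg.validate()


def test_genotype_dimension_mismatch_rejected(small_config, small_trial):
    _, genotypes, _, _, _ = small_trial
    other = SimConfig(**{**small_config.__dict__, "n_lines": small_config.n_lines + 1})
    with pytest.raises(Exception, match="lines"):
        simulate_testcross_trial(other, genotypes)
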