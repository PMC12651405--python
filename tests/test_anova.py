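"""Factorial ANOVA: reference degrees of freedom, SS identities, and
agreement with an independent type-I ANOVA oracle (statsmodels)."""

import numpy as np
import pandas as pd
import pytest

from maizegca import anova_df, joint_combining_anova, per_tester_anova
from maizegca.anova import BalanceError, balanced_anova, cross_partition_ss, \
    JOINT_COMBINING_SOURCES, PER_TESTER_SOURCES
from maizegca.config import ConfigurationError
from conftest import random_balanced_plots


def test_joint_combining_df_reference_dimensions():
    """218 lines, 2 testers, 3 locations, 4 blocks."""
    dfs = anova_df("joint_combining", {"Line": 218, "Tester": 2, "Loc": 3, "Blo": 4})
    assert list(dfs.items()) == [
        ("Loc", 2), ("Blo", 3), ("Line", 217), ("Line × Loc", 434),
        ("Tester", 1), ("Tester × Loc", 2), ("Line × Tester", 217),
        ("Line × Tester × Loc", 434),
    ]


def test_per_tester_df_reference_dimensions():
    """4 blocks, 3 locations, 218 crosses."""
    dfs = anova_df("per_tester", {"Blo": 4, "Loc": 3, "Cro": 218})
    assert list(dfs.items()) == [
        ("Blo", 3), ("Loc", 2), ("Cro", 217), ("Blo × Loc", 6),
        ("Blo × Cro", 651), ("Loc × Cro", 434), ("Blo × Loc × Cro", 1302),
    ]


def test_single_level_factor_gives_zero_df():
    dfs = anova_df("per_tester", {"Blo": 1, "Loc": 3, "Cro": 10})
    assert dfs["Blo"] == 0 and dfs["Blo × Loc"] == 0 and dfs["Blo × Loc × Cro"] == 0


def test_unknown_design_rejected():
    with pytest.raises(ConfigurationError, match="design_name"):
        anova_df("nested_whatever", {"Blo": 2})


def test_df_sum_identity(small_trial):
    _, _, _, plots, _ = small_trial
    tab = joint_combining_anova(plots, "YPP")
    assert sum(r.df for r in tab.rows) + tab.error_row.df == len(plots) - 1
    for r in tab.rows:
        if r.df > 0:
            assert r.ms == pytest.approx(r.ss / r.df)


def test_ss_additivity_and_nonnegativity(small_trial):
    _, _, _, plots, _ = small_trial
    tab = joint_combining_anova(plots, "YPP")
    total = sum(r.ss for r in tab.rows) + tab.error_row.ss
    assert total == pytest.approx(tab.total_ss, rel=1e-8)
    assert all(r.ss >= 0 for r in tab.rows)


def test_constant_data_all_ss_zero():
    plots = random_balanced_plots(np.random.default_rng(0), 4, 2, 2, 2)
    plots["Y"] = 5.0
    tab = joint_combining_anova(plots, "Y")
    assert all(r.ss == pytest.approx(0, abs=1e-18) for r in tab.rows)


def _statsmodels_typ1(df, formula, order):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    return {src: float(tab.loc[key, "sum_sq"]) for src, key in order.items()}


@pytest.mark.parametrize("dims", [(2, 2, 2), (3, 3, 3), (3, 2, 4)])
def test_per_tester_ss_matches_statsmodels(dims):
    """Every source SS matches an independently computed type-I ANOVA on a
    fully crossed balanced layout (they coincide on balanced data)."""
    nb, nl, nc = dims
    rng = np.random.default_rng(sum(dims))
    idx = pd.MultiIndex.from_product(
        [[f"b{i}" for i in range(nb)], [f"l{i}" for i in range(nl)],
         [f"c{i}" for i in range(nc)]], names=["Blo", "Loc", "Cro"])
    df = idx.to_frame(index=False)
    df["y"] = rng.normal(size=len(df))
    tab = balanced_anova(df, PER_TESTER_SOURCES, "y", "per_tester",
                         error_source="Blo × Loc × Cro")
    oracle = _statsmodels_typ1(
        df, "y ~ C(Blo)*C(Loc)*C(Cro)",
        {"Blo": "C(Blo)", "Loc": "C(Loc)", "Cro": "C(Cro)",
         "Blo × Loc": "C(Blo):C(Loc)", "Blo × Cro": "C(Blo):C(Cro)",
         "Loc × Cro": "C(Loc):C(Cro)"})
    for r in tab.rows:
        assert r.ss == pytest.approx(oracle[r.source], rel=1e-9), r.source


def test_joint_ss_matches_statsmodels():
    plots = random_balanced_plots(np.random.default_rng(3), 3, 2, 3, 2)
    tab = joint_combining_anova(plots, "Y")
    df = plots.rename(columns={"line_id": "Line", "tester_id": "Tester",
                               "location": "Loc", "block": "Blo"})
    oracle = _statsmodels_typ1(
        df, "y ~ C(Loc) + C(Blo) + C(Line) + C(Line):C(Loc) + C(Tester) "
            "+ C(Tester):C(Loc) + C(Line):C(Tester) + C(Line):C(Tester):C(Loc)"
            .replace("y", "Y"),
        {"Loc": "C(Loc)", "Blo": "C(Blo)", "Line": "C(Line)",
         "Line × Loc": "C(Line):C(Loc)", "Tester": "C(Tester)",
         "Tester × Loc": "C(Tester):C(Loc)", "Line × Tester": "C(Line):C(Tester)",
         "Line × Tester × Loc": "C(Line):C(Tester):C(Loc)"})
    for r in tab.rows:
        assert r.ss == pytest.approx(oracle[r.source], rel=1e-9), r.source


def test_cross_partition_identity(small_trial):
    """SS(Cross) = SS(Line) + SS(Tester) + SS(Line x Tester)."""
    _, _, _, plots, _ = small_trial
    parts = cross_partition_ss(plots, "YPP")
    assert parts["ss_cross"] == pytest.approx(
        parts["ss_line"] + parts["ss_tester"] + parts["ss_line_x_tester"], rel=1e-10)


def test_per_tester_aggregates_replicates(small_trial):
    _, _, _, plots, _ = small_trial
    tab = per_tester_anova(plots, "PH6WC", "YPP")
    # blocks x locations x lines cells, minus the error stratum
    assert sum(r.df for r in tab.rows) + tab.error_row.df == 2 * 3 * 12 - 1


def test_incomplete_layout_error_lists_cells(small_trial):
    _, _, _, plots, _ = small_trial
    broken = plots[~((plots.line_id == plots.line_id.iloc[0]) &
                     (plots.location == plots.location.iloc[0]))]
    with pytest.raises(BalanceError, match="empty cells"):
        joint_combining_anova(broken, "YPP")


def test_mixed_model_denominator_option(small_trial):
    _, _, _, plots, _ = small_trial
    resid = joint_combining_anova(plots, "YPP", test_against="residual")
    mixed = joint_combining_anova(plots, "YPP", test_against="interaction")
    line_r = resid.row("Line")
    line_m = mixed.row("Line")
    expected_f = line_m.ms / mixed.row("Line × Loc").ms
    assert line_m.f_stat == pytest.approx(expected_f)
    assert line_r.f_stat != pytest.approx(line_m.f_stat)


def test_location_signal_detected_and_null_sources_calibrated():
    """Inject only location effects: Loc is detected at p < 0.01 while the
    null sources reject at roughly the nominal 5% rate."""
    from maizegca import SimConfig, VarianceComponents, simulate_genotypes, \
        simulate_testcross_trial

    loc_detected = 0
    null_reject = []
    n_reps = 300
    for rep in range(n_reps):
        cfg = SimConfig(n_lines=10, n_testers=2, n_locations=3, n_blocks_per_location=2,
                        n_snps=10, n_causal_per_trait=1, traits=("YPP",),
                        marker_effect_scale=0.0,
                        variance_components=VarianceComponents(
                            0.0, 0.0, 0.0, 25.0, 0.0, 0.0, 1.0),
                        seed=3000 + rep)
        g, _ = simulate_genotypes(cfg)
        plots, _ = simulate_testcross_trial(cfg, g)
        tab = per_tester_anova(plots, "PH6WC", "YPP")
        loc_detected += tab.row("Loc").p < 0.01
        for src in ("Blo", "Cro", "Blo × Loc", "Blo × Cro", "Loc × Cro"):
            null_reject.append(tab.row(src).p < 0.05)
    assert loc_detected / n_reps >= 0.95
    rate = np.mean(null_reject)
    assert 0.03 < rate < 0.08
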