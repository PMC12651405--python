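"""NCII (line x tester) combining-ability estimators.

Griffing-style totals arithmetic for a factorial testcross: with f tested
lines, m testers and r replicate plots per cross,

    grand mean   = T.. / (m f r)
    line GCA_i   = T_f(i) / (r m) - T.. / (m f r)
    tester GCA_j = T_m(j) / (r f) - T.. / (m f r)
    SCA_ij       = T_ij / r - T_f(i)/(r m) - T_m(j)/(r f) + T.. / (m f r)

which satisfy the zero-sum identities and reconstruct every cross mean as
grand mean + GCA_i + GCA_j + SCA_ij.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InputError, validate_plot_table


class BalanceError(InputError):
    """Raised when replication is unbalanced across crosses."""


class DesignError(InputError):
    """Raised when the mating design is degenerate (e.g. f < 2)."""


@dataclass
class TestcrossDesign:
    f: int                   # tested lines
    m: int                   # testers
    r: int                   # replicate plots per cross in scope
    line_ids: list[str]
    tester_ids: list[str]

    def __post_init__(self) -> None:
        if self.f < 2:
            raise DesignError(f"need at least 2 tested lines, got {self.f}")
        if self.m < 1 or self.r < 1:
            raise DesignError("need m >= 1 testers and r >= 1 replications")
        if len(set(self.line_ids)) != self.f or len(set(self.tester_ids)) != self.m:
            raise DesignError("line/tester ids must be unique")


@dataclass
class CrossTotals:
    design: TestcrossDesign
    t_cross: pd.DataFrame    # f x m totals T_ij
    t_line: pd.Series        # T_f
    t_tester: pd.Series      # T_m
    grand_total: float


@dataclass
class CombiningAbilityResult:
    trait: str
    scope: str
    grand_mean: float
    gca_lines: pd.Series
    gca_testers: pd.Series
    sca: pd.DataFrame        # lines x testers

    def reconstruct_cross_means(self) -> pd.DataFrame:
        return (self.sca
                .add(self.gca_lines, axis=0)
                .add(self.gca_testers, axis=1)
                + self.grand_mean)

    def to_tidy(self) -> pd.DataFrame:
        """Long CSV-ready form: effect_type in {grand_mean, gca_line, gca_tester, sca}."""
        rows = [{"trait": self.trait, "scope": self.scope, "effect_type": "grand_mean",
                 "line_id": "", "tester_id": "", "value": self.grand_mean}]
        rows += [{"trait": self.trait, "scope": self.scope, "effect_type": "gca_line",
                  "line_id": i, "tester_id": "", "value": v}
                 for i, v in self.gca_lines.items()]
        rows += [{"trait": self.trait, "scope": self.scope, "effect_type": "gca_tester",
                  "line_id": "", "tester_id": j, "value": v}
                 for j, v in self.gca_testers.items()]
        rows += [{"trait": self.trait, "scope": self.scope, "effect_type": "sca",
                  "line_id": i, "tester_id": j, "value": self.sca.loc[i, j]}
                 for i in self.sca.index for j in self.sca.columns]
        return pd.DataFrame(rows)


def enumerate_crosses(line_ids: list[str], tester_ids: list[str]) -> list[tuple[str, str]]:
    """All inter-group crosses of the NCII design (lines x testers)."""
    return list(itertools.product(line_ids, tester_ids))


def partition_into_blocks(crosses: list[tuple[str, str]], n_blocks: int) -> list[list[tuple[str, str]]]:
    """Split the cross list into n_blocks contiguous field blocks of equal size."""
    if len(crosses) % n_blocks != 0:
        raise DesignError(
            f"{len(crosses)} crosses cannot be split evenly into {n_blocks} blocks")
    size = len(crosses) // n_blocks
    return [crosses[b * size:(b + 1) * size] for b in range(n_blocks)]


def _scope_plots(plots: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "pooled":
        return plots
    if scope.startswith("per-location:"):
        loc = scope.split(":", 1)[1]
        sub = plots[plots["location"] == loc]
        if sub.empty:
            raise InputError(f"no plots for location {loc!r}")
        return sub
    raise InputError(f"scope must be 'pooled' or 'per-location:<loc>', got {scope!r}")


def cross_totals(plots: pd.DataFrame, trait: str, scope: str = "pooled") -> CrossTotals:
    """Per-cross, per-line, per-tester and grand totals within a scope."""
    validate_plot_table(plots, traits=[trait])
    sub = _scope_plots(plots, scope)
    counts = sub.pivot_table(index="line_id", columns="tester_id", values=trait,
                             aggfunc="count", fill_value=0)
    r_values = np.unique(counts.to_numpy())
    if len(r_values) != 1 or r_values[0] == 0:
        raise BalanceError(
            f"unequal replication across crosses in scope {scope!r}: counts {sorted(r_values)}")
    r = int(r_values[0])
    t_cross = sub.pivot_table(index="line_id", columns="tester_id", values=trait, aggfunc="sum")
    t_cross = t_cross.sort_index().sort_index(axis=1)
    design = TestcrossDesign(
        f=t_cross.shape[0], m=t_cross.shape[1], r=r,
        line_ids=list(t_cross.index), tester_ids=list(t_cross.columns))
    return CrossTotals(
        design=design,
        t_cross=t_cross,
        t_line=t_cross.sum(axis=1),
        t_tester=t_cross.sum(axis=0),
        grand_total=float(t_cross.to_numpy().sum()),
    )


def estimate_combining_ability(
    plots: pd.DataFrame,
    trait: str,
    scope: str = "pooled",
    on_unbalanced: str = "raise",
) -> CombiningAbilityResult:
    """Grand mean, line/tester GCA and SCA for one trait from plot totals.

    ``on_unbalanced='means'`` falls back to per-cross means (r = 1) with a
    warning instead of raising when replication is uneven.
    """
    try:
        totals = cross_totals(plots, trait, scope)
    except BalanceError:
        if on_unbalanced != "means":
            raise
        warnings.warn("unbalanced replication: falling back to cross means (r = 1)",
                      stacklevel=2)
        sub = _scope_plots(plots, scope)
        means = sub.pivot_table(index="line_id", columns="tester_id", values=trait,
                                aggfunc="mean").sort_index().sort_index(axis=1)
        if means.isna().any().any():
            raise InputError("missing crosses in scope; cannot estimate effects") from None
        design = TestcrossDesign(f=means.shape[0], m=means.shape[1], r=1,
                                 line_ids=list(means.index), tester_ids=list(means.columns))
        totals = CrossTotals(design, means, means.sum(axis=1), means.sum(axis=0),
                             float(means.to_numpy().sum()))
    d = totals.design
    grand_mean = totals.grand_total / (d.m * d.f * d.r)
    gca_lines = totals.t_line / (d.r * d.m) - grand_mean
    gca_testers = totals.t_tester / (d.r * d.f) - grand_mean
    sca = (totals.t_cross / d.r).sub(totals.t_line / (d.r * d.m), axis=0) \
        .sub(totals.t_tester / (d.r * d.f), axis=1) + grand_mean
    return CombiningAbilityResult(trait=trait, scope=scope, grand_mean=float(grand_mean),
                                  gca_lines=gca_lines, gca_testers=gca_testers, sca=sca)


def combining_from_means(
    cross_means: pd.DataFrame, trait: str, scope: str = "blup-means"
) -> CombiningAbilityResult:
    """Estimators applied to a complete lines x testers table of adjusted
    (e.g. BLUP) cross means, i.e. the r = 1 case."""
    if cross_means.isna().any().any():
        raise InputError("cross-mean table has missing cells")
    long = cross_means.rename_axis("line_id").reset_index().melt(
        id_vars="line_id", var_name="tester_id", value_name=trait)
    long["location"] = "adj"
    long["block"] = "B1"
    result = estimate_combining_ability(long, trait, scope="pooled")
    return dataclasses.replace(result, scope=scope)


def rank_by_gca(result: CombiningAbilityResult, top_k: int, direction: str = "high") -> list[str]:
    """Top-k lines by GCA; ties broken by line id (lexicographic).

    ``direction`` is explicit because trait favorability differs by trait
    (for tassel traits a more negative GCA is the better breeding value).
    """
    if direction not in ("high", "low"):
        raise InputError("direction must be 'high' or 'low'")
    if top_k > len(result.gca_lines):
        raise InputError(f"top_k={top_k} exceeds number of lines {len(result.gca_lines)}")
    sign = -1.0 if direction == "high" else 1.0
    order = sorted(result.gca_lines.items(), key=lambda kv: (sign * kv[1], kv[0]))
    return [line for line, _ in order[:top_k]]
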