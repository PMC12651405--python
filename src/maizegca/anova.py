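"""Balanced factorial ANOVA for the testcross trial.

Two layouts are produced:

* per-tester joint ANOVA — Blo x Loc x Cro, with the three-way interaction
  serving as the error stratum when each cell holds a single plot;
* joint combining-ability ANOVA — Loc, Blo, Line, Line x Loc, Tester,
  Tester x Loc, Line x Tester, Line x Tester x Loc, with the pooled
  remainder (block-interaction strata) as error.

Sums of squares come from the standard inclusion-exclusion over marginal
means, valid for complete balanced data; the Line, Tester and Line x Tester
SS together partition the between-cross SS (the GCA/SCA decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import prod

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError
from .containers import InputError, validate_plot_table


class BalanceError(InputError):
    """Raised when a layout is incomplete or unequally replicated."""


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f_stat: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    design_name: str
    rows: list[AnovaRow]
    error_row: AnovaRow
    total_df: int
    total_ss: float

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        def stars(p):
            if p is None:
                return ""
            return "**" if p < 0.01 else ("*" if p < 0.05 else "")

        records = [
            {"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms,
             "f": r.f_stat, "p": r.p, "sig": stars(r.p)}
            for r in self.rows
        ]
        records.append({"source": self.error_row.source, "df": self.error_row.df,
                        "ss": self.error_row.ss, "ms": self.error_row.ms,
                        "f": None, "p": None, "sig": ""})
        return pd.DataFrame(records)


# ordered sources of the two reported table layouts
PER_TESTER_SOURCES: list[tuple[str, tuple[str, ...]]] = [
    ("Blo", ("Blo",)),
    ("Loc", ("Loc",)),
    ("Cro", ("Cro",)),
    ("Blo × Loc", ("Blo", "Loc")),
    ("Blo × Cro", ("Blo", "Cro")),
    ("Loc × Cro", ("Loc", "Cro")),
    ("Blo × Loc × Cro", ("Blo", "Loc", "Cro")),
]

JOINT_COMBINING_SOURCES: list[tuple[str, tuple[str, ...]]] = [
    ("Loc", ("Loc",)),
    ("Blo", ("Blo",)),
    ("Line", ("Line",)),
    ("Line × Loc", ("Line", "Loc")),
    ("Tester", ("Tester",)),
    ("Tester × Loc", ("Tester", "Loc")),
    ("Line × Tester", ("Line", "Tester")),
    ("Line × Tester × Loc", ("Line", "Tester", "Loc")),
]

_DESIGNS = {"per_tester": PER_TESTER_SOURCES, "joint_combining": JOINT_COMBINING_SOURCES}


def anova_df(design_name: str, levels: dict[str, int]) -> dict[str, int]:
    """Degrees of freedom per table source: main effects get levels - 1,
    interactions the product of their components' dfs."""
    if design_name not in _DESIGNS:
        raise ConfigurationError(f"unknown design_name {design_name!r}; "
                                 f"expected one of {sorted(_DESIGNS)}")
    out: dict[str, int] = {}
    for source, factors in _DESIGNS[design_name]:
        missing = [f for f in factors if f not in levels]
        if missing:
            raise ConfigurationError(f"levels missing for factors {missing}")
        out[source] = prod(levels[f] - 1 for f in factors)
    return out


def _check_complete_balanced(df: pd.DataFrame, factors: list[str]) -> int:
    """Return the common cell count; raise listing missing cells otherwise."""
    counts = df.groupby(factors, observed=True).size()
    level_sets = [df[f].unique() for f in factors]
    n_cells = prod(len(s) for s in level_sets)
    if len(counts) != n_cells:
        full = pd.MultiIndex.from_product(level_sets, names=factors)
        missing = full.difference(counts.index)
        shown = list(missing[:10])
        raise BalanceError(
            f"incomplete layout: {len(missing)} empty cells, e.g. {shown}")
    if counts.nunique() != 1:
        raise BalanceError(
            f"unequal cell counts: {sorted(counts.unique())}")
    return int(counts.iloc[0])


def _term_effect(df: pd.DataFrame, term: tuple[str, ...], response: str) -> np.ndarray:
    """Per-observation effect of a term by inclusion-exclusion of marginal means."""
    grand = df[response].mean()
    eff = np.zeros(len(df))
    for k in range(len(term) + 1):
        for sub in combinations(term, k):
            sign = (-1) ** (len(term) - k)
            if sub:
                m = df.groupby(list(sub), observed=True)[response].transform("mean").to_numpy()
            else:
                m = grand
            eff += sign * m
    return eff


def balanced_anova(
    df: pd.DataFrame,
    sources: list[tuple[str, tuple[str, ...]]],
    response: str,
    design_name: str,
    error_source: str | None = None,
    f_denominators: dict[str, str] | None = None,
) -> AnovaTable:
    """Balanced complete-layout ANOVA over the given ordered sources.

    If ``error_source`` names one of the sources, that term is the error
    stratum (single-observation-per-cell layouts); otherwise the error is
    the remainder total SS - sum(source SS). ``f_denominators`` may map a
    source to another source whose MS is its F denominator (mixed-model
    convention); default is the error MS.
    """
    factors = sorted({f for _, fs in sources for f in fs})
    _check_complete_balanced(df, factors)
    y = df[response].to_numpy(dtype=float)
    n = len(df)
    total_ss = float(((y - y.mean()) ** 2).sum())
    total_df = n - 1
    levels = {f: df[f].nunique() for f in factors}
    dfs = {s: prod(levels[f] - 1 for f in fs) for s, fs in sources}

    rows: list[AnovaRow] = []
    for source, fs in sources:
        eff = _term_effect(df, fs, response)
        ss = float((eff ** 2).sum())
        d = dfs[source]
        rows.append(AnovaRow(source=source, df=d, ss=ss, ms=ss / d if d > 0 else 0.0))

    if error_source is not None:
        err = next(r for r in rows if r.source == error_source)
        rows = [r for r in rows if r.source != error_source]
        error_row = AnovaRow("Error (" + error_source + ")", err.df, err.ss, err.ms)
    else:
        used_ss = sum(r.ss for r in rows)
        used_df = sum(r.df for r in rows)
        err_df = total_df - used_df
        err_ss = max(total_ss - used_ss, 0.0)
        if err_df <= 0:
            raise BalanceError("no residual degrees of freedom for an error term")
        error_row = AnovaRow("Error", err_df, err_ss, err_ss / err_df)

    ms_by_source = {r.source: r for r in rows}
    f_denominators = f_denominators or {}
    for r in rows:
        denom = error_row
        if r.source in f_denominators:
            denom = ms_by_source[f_denominators[r.source]]
        if denom.ms > 0 and r.df > 0 and denom.df > 0:
            r.f_stat = r.ms / denom.ms
            r.p = float(stats.f.sf(r.f_stat, r.df, denom.df))
    return AnovaTable(design_name=design_name, rows=rows, error_row=error_row,
                      total_df=total_df, total_ss=total_ss)


def per_tester_anova(plots: pd.DataFrame, tester_id: str, trait: str) -> AnovaTable:
    """Blo x Loc x Cro joint ANOVA for the crosses of one tester.

    Replicate plots within a (block, location, cross) cell are averaged
    first; the three-way interaction is the error stratum.
    """
    validate_plot_table(plots, traits=[trait])
    sub = plots[plots["tester_id"] == tester_id]
    if sub.empty:
        raise InputError(f"no plots for tester {tester_id!r}")
    agg = (sub.groupby(["block", "location", "line_id"], observed=True)[trait]
           .mean().reset_index()
           .rename(columns={"block": "Blo", "location": "Loc", "line_id": "Cro"}))
    return balanced_anova(agg, PER_TESTER_SOURCES, trait,
                          design_name=f"per_tester:{tester_id}",
                          error_source="Blo × Loc × Cro")


def joint_combining_anova(
    plots: pd.DataFrame, trait: str, test_against: str = "residual"
) -> AnovaTable:
    """Loc/Blo/Line/Tester joint combining-ability ANOVA for one trait.

    The error pools the block-interaction strata (every term not listed
    as a named source).
    ``test_against='interaction'`` tests Line and Tester against their
    x Loc interaction MS instead of the residual.
    """
    validate_plot_table(plots, traits=[trait])
    df = plots.rename(columns={"line_id": "Line", "tester_id": "Tester",
                               "location": "Loc", "block": "Blo"})
    if df["Line"].nunique() < 2:
        raise InputError("need at least 2 lines")
    denoms = None
    if test_against == "interaction":
        denoms = {"Line": "Line × Loc", "Tester": "Tester × Loc"}
    elif test_against != "residual":
        raise ConfigurationError("test_against must be 'residual' or 'interaction'")
    return balanced_anova(df, JOINT_COMBINING_SOURCES, trait,
                          design_name="joint_combining", f_denominators=denoms)


def cross_partition_ss(plots: pd.DataFrame, trait: str) -> dict[str, float]:
    """SS of the 'cross' factor (lines x testers collapsed to one factor)
    next to its Line + Tester + Line x Tester decomposition."""
    df = plots.copy()
    df["Cross"] = df["line_id"].astype(str) + "×" + df["tester_id"].astype(str)
    eff = _term_effect(df, ("Cross",), trait)
    ss_cross = float((eff ** 2).sum())
    table = joint_combining_anova(plots, trait)
    return {
        "ss_cross": ss_cross,
        "ss_line": table.row("Line").ss,
        "ss_tester": table.row("Tester").ss,
        "ss_line_x_tester": table.row("Line × Tester").ss,
    }
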