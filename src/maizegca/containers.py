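"""In-memory containers shared across the pipeline.

The plot table is a plain pandas DataFrame in long format with columns
``line_id, tester_id, location, block`` followed by one column per trait;
each (line, tester, location, block) key appears at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLOT_KEY_COLUMNS = ["line_id", "tester_id", "location", "block"]


class InputError(ValueError):
    """Raised for malformed or inconsistent inputs."""


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix for an inbred panel.

    ``dosages`` counts alternate alleles per line (0/1/2), with ``np.nan``
    for missing calls. ``variants`` carries one row per variant with at
    least columns ``snp_id, chrom, pos, ref, alt, n_alleles`` (``n_alleles``
    flags multi-allelic records for QC) and, for simulated panels, a
    ``causal_trait`` column naming the trait a causal SNP acts on ("" if
    neutral).
    """

    dosages: np.ndarray
    line_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D lines x variants array")
        if self.dosages.shape[0] != len(self.line_ids):
            raise InputError("dosages row count must match line_ids")
        if self.dosages.shape[1] != len(self.variants):
            raise InputError("dosages column count must match variants table")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["snp_id"] == snp_id]
        if len(idx) == 0:
            raise InputError(f"unknown SNP id: {snp_id}")
        return self.dosages[:, self.variants.index.get_loc(idx[0])]

    def equals(self, other: "GenotypeMatrix") -> bool:
        same_calls = np.array_equal(self.dosages, other.dosages, equal_nan=True)
        return (
            same_calls
            and self.line_ids == other.line_ids
            and self.variants[["snp_id", "chrom", "pos", "ref", "alt"]]
            .reset_index(drop=True)
            .equals(other.variants[["snp_id", "chrom", "pos", "ref", "alt"]].reset_index(drop=True))
        )


@dataclass
class TruthRecord:
    """Ground-truth effects behind one simulated trait (for recovery tests)."""

    trait: str
    true_gca_line: pd.Series          # indexed by line_id, sums to 0
    true_gca_tester: pd.Series        # indexed by tester_id, sums to 0
    true_sca: pd.DataFrame            # lines x testers, rows/cols sum to 0
    causal_snp_ids: list[str] = field(default_factory=list)
    causal_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    loc_effects: pd.Series | None = None
    block_effects: pd.DataFrame | None = None      # (location, block) -> effect
    line_x_loc: pd.DataFrame | None = None         # lines x locations


def validate_plot_table(plots: pd.DataFrame, traits: list[str] | None = None) -> list[str]:
    """Check plot-table structure; return the trait column names."""
    missing = [c for c in PLOT_KEY_COLUMNS if c not in plots.columns]
    if missing:
        raise InputError(f"plot table missing key columns: {missing}")
    if plots.duplicated(PLOT_KEY_COLUMNS).any():
        raise InputError("duplicate (line, tester, location, block) keys in plot table")
    found = [c for c in plots.columns if c not in PLOT_KEY_COLUMNS]
    if traits is not None:
        absent = [t for t in traits if t not in found]
        if absent:
            raise InputError(f"traits absent from plot table: {absent}")
        found = list(traits)
    if not found:
        raise InputError("plot table has no trait columns")
    for t in found:
        vals = plots[t].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise InputError(f"non-finite values in trait column {t}")
    return found
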