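"""Configuration objects for the synthetic trial generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

# The 16 yield-related traits measured on the testcross population.
TRAITS = (
    "PH", "EH", "SDR", "SL", "TBN", "TL", "EL", "ED",
    "SD", "KRN", "KNPR", "HKW", "KL", "KW", "GT", "YPP",
)

ERAS = ("AGE1", "AGE2", "AGE3")


class ConfigurationError(ValueError):
    """Raised when a configuration field violates its constraints."""


@dataclass
class VarianceComponents:
    """Generative variance components of the plot model, trait units squared."""

    var_gca_line: float = 4.0
    var_gca_tester: float = 1.0
    var_sca: float = 1.0
    var_loc: float = 4.0
    var_block_within_loc: float = 0.5
    var_line_x_loc: float = 1.0
    var_residual: float = 2.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigurationError(f"variance component {name} must be >= 0, got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic NCII testcross trial.

    Defaults mirror the study design: 218 tested inbred lines crossed to
    2 testers (436 hybrids), grown at 3 locations in a replicated
    randomized-complete-block layout, lines split roughly evenly over
    three breeding eras, with causal minor-allele frequencies shifting
    monotonically across eras.
    """

    n_lines: int = 218
    n_testers: int = 2
    n_locations: int = 3
    n_blocks_per_location: int = 3
    era_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_snps: int = 2000
    n_causal_per_trait: int = 5
    # signed minor-allele-frequency increment per era step at causal SNPs;
    # 0.055/step gives the ~11% rise over AGE1->AGE3 seen for favorable alleles
    era_freq_shift: float = 0.055
    causal_base_freq: float = 0.2
    variance_components: VarianceComponents = field(default_factory=VarianceComponents)
    marker_effect_scale: float = 0.5
    missing_rate: float = 0.02
    het_rate: float = 0.02
    grand_mean: float = 100.0
    traits: tuple[str, ...] = TRAITS
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lines", "n_testers", "n_locations", "n_blocks_per_location",
                     "n_snps", "n_causal_per_trait"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.era_proportions) != 3:
            raise ConfigurationError("era_proportions must have exactly 3 entries")
        if abs(sum(self.era_proportions) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"era_proportions must sum to 1, got {sum(self.era_proportions)!r}")
        if any(p < 0 for p in self.era_proportions):
            raise ConfigurationError("era_proportions entries must be >= 0")
        if not (0.0 <= self.missing_rate < 0.2):
            raise ConfigurationError(f"missing_rate must be in [0, 0.2), got {self.missing_rate}")
        if not (0.0 <= self.het_rate < 0.1):
            raise ConfigurationError(f"het_rate must be in [0, 0.1), got {self.het_rate}")
        if not (0.0 <= self.causal_base_freq <= 1.0):
            raise ConfigurationError("causal_base_freq must be in [0, 1]")
        if self.n_causal_per_trait * len(self.traits) > self.n_snps:
            raise ConfigurationError(
                "n_snps too small for n_causal_per_trait non-overlapping causal SNPs per trait")
        if not self.traits:
            raise ConfigurationError("traits must be non-empty")
        self.variance_components.validate()

    @property
    def line_ids(self) -> list[str]:
        width = len(str(self.n_lines))
        return [f"L{str(i + 1).zfill(width)}" for i in range(self.n_lines)]

    @property
    def tester_ids(self) -> list[str]:
        # the study's two testers come first; extras get generic names
        named = ["PH6WC", "PH4CV"]
        ids = named[: self.n_testers]
        ids += [f"T{i + 1}" for i in range(len(ids), self.n_testers)]
        return ids

    @property
    def location_ids(self) -> list[str]:
        named = ["LN", "JL", "HLJ"]  # Shenyang, Gongzhuling, Harbin
        ids = named[: self.n_locations]
        ids += [f"E{i + 1}" for i in range(len(ids), self.n_locations)]
        return ids


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate-mode or ingest-mode)."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: Optional[SimConfig] = None
    plots_csv: Optional[str] = None
    vcf: Optional[str] = None
    eras_csv: Optional[str] = None
    traits: Optional[list[str]] = None         # None -> all traits present
    gca_scope: str = "blup"                    # "blup" or "pooled"
    gwas_threshold: float = 3.5e-5
    gwas_n_pcs: int = 3
    trend_test: str = "welch"                  # or "mannwhitney"
    # traits where a LOWER GCA is favorable (tassel / stature traits)
    lower_is_better: tuple[str, ...] = ("TBN", "TL", "PH", "EH", "SDR")

    def validate(self) -> None:
        ingest = [self.plots_csv, self.vcf, self.eras_csv]
        has_ingest = any(p is not None for p in ingest)
        if self.simulate is not None and has_ingest:
            raise ConfigurationError("provide either simulate config or input paths, not both")
        if self.simulate is None and not all(p is not None for p in ingest):
            raise ConfigurationError(
                "ingest mode needs all of plots_csv, vcf, eras_csv (or a simulate config)")
        if self.simulate is not None:
            self.simulate.validate()
        if not (0.0 < self.gwas_threshold < 1.0):
            raise ConfigurationError("gwas_threshold must be in (0, 1)")
        if self.gca_scope not in ("blup", "pooled"):
            raise ConfigurationError("gca_scope must be 'blup' or 'pooled'")
        if self.trend_test not in ("welch", "mannwhitney"):
            raise ConfigurationError("trend_test must be 'welch' or 'mannwhitney'")
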