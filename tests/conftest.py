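import numpy as np
import pandas as pd
import pytest

from maizegca import SimConfig, VarianceComponents, simulate_genotypes, simulate_testcross_trial


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_lines=12, n_testers=2, n_locations=3, n_blocks_per_location=2,
        n_snps=100, n_causal_per_trait=2, traits=("YPP", "TBN"),
        missing_rate=0.02, het_rate=0.02, seed=11,
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    genotypes, eras = simulate_genotypes(small_config)
    plots, truth = simulate_testcross_trial(small_config, genotypes)
    return small_config, genotypes, eras, plots, truth


@pytest.fixture
def toy_plots_2x2() -> pd.DataFrame:
    """Two lines x two testers, one plot each; cross means [[1,2],[3,4]]."""
    return pd.DataFrame({
        "line_id": ["L1", "L1", "L2", "L2"],
        "tester_id": ["T1", "T2", "T1", "T2"],
        "location": ["E1"] * 4,
        "block": ["B1"] * 4,
        "Y": [1.0, 2.0, 3.0, 4.0],
    })


def random_balanced_plots(rng: np.random.Generator, f: int, m: int,
                          n_loc: int, n_block: int, trait: str = "Y") -> pd.DataFrame:
    """A complete balanced plot table with iid normal values."""
    idx = pd.MultiIndex.from_product(
        [[f"L{i}" for i in range(f)], [f"T{j}" for j in range(m)],
         [f"E{k}" for k in range(n_loc)], [f"B{b}" for b in range(n_block)]],
        names=["line_id", "tester_id", "location", "block"])
    df = idx.to_frame(index=False)
    df[trait] = rng.normal(size=len(df))
    return df
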