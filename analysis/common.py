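"""Shared settings for the numbered analysis scripts.

The scripts form one narrative run at the reference design scale
(218 lines x 2 testers x 3 locations x 3 blocks): 01 writes the synthetic
inputs, 02-06 each read the previous stage's outputs from RESULTS and add
their own. Run them in order from the repository root:

    python analysis/01_simulate.py
    python analysis/02_blup.py
    ...
"""

from pathlib import Path

from maizegca import SimConfig

SEED = 20240218
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
INPUTS = RESULTS / "inputs"
PLOTS = RESULTS / "figures"

# Reference-scale design; a trait subset keeps the full narrative run to minutes.
SIM = SimConfig(
    n_lines=218,
    n_testers=2,
    n_locations=3,
    n_blocks_per_location=3,
    n_snps=2000,
    n_causal_per_trait=5,
    traits=("YPP", "HKW", "PH", "EH", "TBN", "ED", "EL", "KRN"),
    # strengthen the era-structured causal signal so the era narrative
    # (stage 06) has something to show at this panel size
    era_freq_shift=0.12,
    marker_effect_scale=1.0,
    seed=SEED,
)

TRAITS = list(SIM.traits)
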