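# Methods

This document records the statistical models, the simulator's assumptions,
the numerical choices and the design decisions behind `maizegca`.

## 1. Design and notation

An NCII (line × tester) factorial: `f` tested inbred lines crossed to `m`
testers gives `f·m` hybrids; each hybrid is grown in `b` randomized
complete blocks at each of `l` locations, one plot per block, so
`r = b·l` plots per cross. The package's reference scale is
`f = 218, m = 2, l = 3, b = 3` → 436 hybrids and 3,924 plots;
`enumerate_crosses`/`partition_into_blocks` also reproduce the 4 × 109
incomplete-block partition of the 436 crosses used when a single location
cannot hold them all.

## 2. Combining ability (`combining.py`)

Griffing-style totals estimators on a balanced table (`T` = totals):

```
grand = T/(m·f·r)
ĝ_f   = T_f/(r·m) − grand
ĝ_m   = T_m/(r·f) − grand
ŝ_fm  = T_fm/r − T_f/(r·m) − T_m/(r·f) + grand
```

Identities enforced and tested: `Σĝ_f = Σĝ_m = 0`, SCA rows/columns sum to
zero, and `cell mean = grand + ĝ_f + ĝ_m + ŝ_fm` exactly. On balanced data
these equal the cell-means decomposition; the test suite verifies equality
to 1e-10 against an independently coded cell-means oracle on 1,000 random
balanced tables. Unbalanced tables raise `BalanceError` by default;
`on_unbalanced="means"` falls back to the (clearly-labeled) cell-means
route with a warning. `combining_from_means` applies the same decomposition
to a lines × testers table of BLUP hybrid values (`scope="blup-means"`),
which is the pipeline default; `gca_scope="pooled"` uses raw plot totals.

Rankings are direction-aware: for stature/tassel traits
(`TBN, TL, PH, EH, SDR` by default) a *lower* GCA is favorable. Ties break
lexicographically for determinism.

## 3. Factorial ANOVA (`anova.py`)

Sums of squares come from inclusion–exclusion over marginal means, valid
for complete balanced layouts (checked; incomplete layouts raise with a
list of empty cells). Two reported layouts:

- **Per tester** `Blo × Loc × Cro` on cell means (replicate plots within a
  block×location×cross cell are averaged first); the three-way interaction
  is the error stratum. At `b = 4, l = 3, f = 218` the degrees of freedom
  are 3/2/217/6/651/434/1302, the layout's reference dimensions.
- **Joint combining** `Loc, Blo, Line, Line×Loc, Tester, Tester×Loc,
  Line×Tester, Line×Tester×Loc` with the pooled remainder (all
  block-interaction strata) as error — DFs 2/3/217/434/1/2/217/434 at the
  same scale. `test_against="interaction"` tests Line and Tester against
  their ×Loc interaction MS (the mixed-model convention); the default is
  the pooled residual, a deliberate, documented choice.

`cross_partition_ss` verifies
`SS(Cross) = SS(Line) + SS(Tester) + SS(Line×Tester)`. The suite also
checks every SS against statsmodels' type-I ANOVA (they coincide on
balanced data) and against a literal nested-loop brute force.

## 4. Multi-environment BLUP (`blup.py`)

Model per trait, long format (`hybrid, env, rep, y`):

```
y = μ + Env_j (fixed, sum-coded) + Hybrid_i + (Hybrid×Env)_ij
    + (Env×Rep)_jn + e,    Hybrid ~ N(0, σ²_H), H×E ~ N(0, σ²_HE),
                           E×R ~ N(0, σ²_ER), e ~ N(0, σ²_e)
```

−2 log L_R is evaluated through the Woodbury identity:
`V⁻¹ = (I − Z W⁻¹ Z′)/σ²_e` with `W = Z′Z + σ²_e G⁻¹` factorized once per
evaluation by sparse LU; `log|V| = (n−q)·log σ²_e + Σ log g + log|W|`.
Minimization is L-BFGS-B over log variances (deterministic start: the
phenotypic variance split equally across the four components; bounds
log σ²_y ± [−18, +6]; `ftol = 1e-13`, `gtol = 1e-10`, ≤ 500 iterations).
Components driven to the lower bound are clamped to exactly zero with a
warning. BLUPs solve the mixed-model equations at the estimates; blocks
with zero variance are shrunk fully to zero.

**Checked invariants.** At fixed variances with only the hybrid component
active, the solver reproduces the balanced closed form
`û_i = k·(ȳ_i − ȳ), k = σ²_H/(σ²_H + σ²_e/n)` to 1e-8. The recorded
objective history is monotone non-increasing over accepted iterates.
Adding a constant to one environment's data is absorbed by the fixed
effects and leaves hybrid BLUPs unchanged (exactly at fixed variances).

**Numerical reproducibility limit.** The restricted likelihood is nearly
flat between `σ²_H` and `σ²_HE` at these problem sizes, and L-BFGS-B uses
finite-difference gradients, so REML *point estimates* move by ~1e-3
relative under last-ulp input perturbations (e.g. a CSV round-trip of the
plot table). Identical inputs are byte-deterministic. Tests that compare
REML refits across perturbed inputs therefore use ~1e-2 tolerances, while
fixed-variance identities are asserted at 1e-8. Recovery: on simulated
trials (218 hybrids, 4 environments, 3 reps; σ² = 4/1/0.5/2) the fitted
`σ²_H, σ²_HE, σ²_e` fall within 25% of truth in ≥ 90 of 100 replicates.
`σ²_ER` is estimated but not scored: with any practical number of env×rep
levels its chi-square sampling error alone exceeds 25%.

## 5. GWAS (`gwas.py`)

QC retains variants that are (in application order) biallelic, have
missing rate < 0.2, carry the minor allele in ≥ 5 lines, have
heterozygosity < 0.1, and have MAF > 0.05 (MAF ≤ 0.05 removed); removal
counts are reported per criterion. Note the ordering interaction: a
monomorphic variant is caught by the carrier filter before the MAF filter,
and on panels of ≲ 50 lines a variant with ≥ 5 minor-allele carriers can
never have MAF ≤ 0.05, so the MAF criterion only fires on larger panels.

Association is a per-SNP fixed-effect linear model: GCA regressed on
additive dosage (het = 1) with the top-3 principal components of the
mean-imputed, centered dosage matrix as structure covariates. This is a
deliberately transparent substitute for multi-locus model-selection
methods (e.g. BLINK): exact, deterministic, easy to calibrate — and a
documented caveat wherever results are written. With complete genotypes
the implementation residualizes `y` and all dosages on `[1, PCs]` once
(QR) and runs the per-variant simple regression on residuals, which yields
the identical t-test as the full OLS (verified against a per-variant
`lstsq` oracle); with missing calls it falls back to per-variant OLS,
dropping missing lines for that variant only. Degenerate variants
(no dosage variance) get `p = 1` and a flag; constant GCA input returns
all `p = 1` with a caveat. Null calibration: the fraction of p < 0.05 on
null simulations (218 lines, 5,000 SNPs, 4 replicates) lies in
[0.04, 0.06].

Threshold presets: `default = 3.5e-5`, `log10_6 = 1e-6`, and a
`bonferroni_full_panel = 0.05/15,232,270` for a full resequencing panel.

## 6. Era trends and elite alleles (`trends.py`)

Lines carry release-era labels AGE1 < AGE2 < AGE3. `gca_trend` summarizes
per-era GCA (n, mean, sd) and tests (AGE1,AGE2), (AGE2,AGE3), (AGE1,AGE3)
with Welch's t by default (cohorts differ in size and spread; Mann-Whitney
available), starring `ns/*/**` at 0.05/0.01. Identical constant groups
give p = 1; eras with < 2 values are `na`. Type-I error is calibrated
(~5% at the 0.05 level over 1,000 null replicates).

`allele_trajectory` follows the two homozygote classes of a SNP across
eras — heterozygous and missing calls are excluded (inbred-line
convention) — with per-class frequency, n and GCA summaries, flagging
classes absent in an era and eras with no homozygous calls.
`elite_allele_report` labels the favorable homozygote per SNP as the class
with the better n-weighted pooled GCA mean in the trait's favorable
direction, reports its AGE1→AGE3 frequency change, and flags ties.

## 7. Simulator (`simulate.py`)

Genotypes: inbred lines drawn per era with causal-SNP alt frequency
`base + k·shift` for era k = 0,1,2 (clamped to [0.01, 0.99], except exact
0/1 are preserved so "absent in AGE1" scenarios are constructible);
non-causal SNPs have a common random frequency. Heterozygous and missing
calls are injected at configurable low rates. Phenotype truth per trait:
line GCA = centered causal-marker score plus a polygenic top-up scaled to
the configured `var_gca_line`; tester GCA and double-centered SCA drawn at
their configured variances; location, block-within-location and line×loc
effects likewise; plot value = grand mean + sum of effects + N(0, σ²_e).
All truth tables are returned (`TruthRecord`) so estimators can be scored
against them. Residual variance calibration, zero-sum truth identities and
null homogeneity of per-era frequencies at `shift = 0` are tested.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent), dominance/epistasis in the genetic architecture, selection
within eras, heterotic-group structure, or unbalanced/missing plots.

Two auxiliary generators exist because the main generator's truth is
variance-parameterized (era-mean structure would break the zero-sum GCA
identity): `simulate_era_gca(era_means, sd, n_per_era, seed)` draws GCA
directly with configured era means, and
`simulate_hybrid_trial(n_hybrids, n_env, n_reps, …)` draws directly from
the BLUP model for REML recovery studies.

Determinism: one `SeedSequence(seed)` spawns independent child streams for
genotypes and trial noise; same seed → bit-identical outputs.

## 8. Pipeline, CLI and outputs

`run_pipeline(RunConfig)` chains simulate/ingest → BLUP → combining →
ANOVA → GWAS → trends, writing CSVs plus a JSON manifest (inputs with
SHA-256, stages completed, QC counts, caveats; on failure the manifest
records the failed stage and the error). Outputs contain no timestamps so
reruns are byte-identical. The `maizegca` CLI wraps each stage and
`run-all` drives the whole pipeline from YAML.

## 9. Parameter defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| `n_lines / n_testers / n_locations` | 218 / 2 / 3 | the reference design scale |
| `n_blocks_per_location` | 3 | RCBD reps per location; ANOVA DF helpers also accept 4 (the reference single-location layout) |
| `era_proportions` | thirds | roughly equal release-era cohorts |
| `missing_rate / het_rate` | 0.02 / 0.02 | typical post-imputation inbred panels; both well under the QC cutoffs |
| variance components | 4/1/1/4/0.5/1/2 | line GCA dominant, visible G×E, residual of the same order as SCA |
| `gwas_threshold` | 3.5e-5 | the default screening threshold; `log10_6` and full-panel Bonferroni provided |
| `gwas_n_pcs` | 3 | small panels need few structure axes; 0 disables |
| REML `ftol` | 1e-13 | resolves the flat likelihood to ~1e-3 in components (see §4) |

## 10. Limitations

- Griffing estimators and the factorial ANOVA require complete balanced
  data; the means fallback and the BLUP route are the supported paths for
  unbalanced reality.
- Single-marker GWAS ignores LD and multi-locus effects; hit lists are
  screening output, not fine-mapping.
- The elite-allele label is an in-sample association, sensitive to small
  per-class n in early eras (class n is reported alongside).
- REML variance components at this scale carry ~10% sampling error;
  downstream shrinkage differences of that order are expected.
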