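# Methods

`clpnet` implements a two-wave **cross-lagged panel network** (CLPN) analysis
of parent–adolescent depressive symptoms, together with the synthetic data,
robustness and comparison machinery needed to use and validate it.

## The model

Let `y₁, y₂ ∈ ℝ¹⁶` be the CES-D-8 item responses of one dyad (8 child + 8
parent items) at waves T1 and T2, reverse-scored so higher is always worse and
z-scored per item. For each T2 item *j* the package fits a penalized linear
regression

    y₂ⱼ = Σᵢ Bᵢⱼ y₁ᵢ + Σₖ γₖⱼ xₖ + ε,

minimizing `(1/2n)‖y − Xβ‖² + λ Σ pfᵢ|βᵢ|`. The 16 symptom predictors carry
penalty factor 1; the demographic covariates `x` (child age, ethnicity
dummy, family income, parental-education dummies) carry penalty factor 0 by
default — they are confounders to adjust for, not edges to select. The 16
nodewise fits assemble the directed weight matrix `B̂` (row = T1 source,
column = T2 target): the diagonal holds autoregressive paths, off-diagonal
entries are cross-lagged effects, and entries crossing the parent/child
community are *bridging* edges, the transmission pathways of interest.

λ is chosen per outcome node by K-fold cross-validation (default 10 folds,
drawn once per fit from `fold_seed` and shared across the 16 regressions)
over a 50-point log grid from λ_max down to λ_max·10⁻³, taking the
CV-minimum by default (`lambda_rule="1se"` is available and markedly more
conservative). With unpenalized covariates, λ_max is computed on the
residual from the covariate-only least-squares fit, so the grid still starts
at an all-zero symptom model. The solver is cyclic coordinate descent with
soft-thresholding on the Gram matrix (`XᵀX/n`), converging when the largest
coefficient change in a sweep falls below 1e-7; working on the Gram form
makes a sweep O(p²) regardless of n, which is what allows thousands of full
re-fits inside the bootstrap and case-dropping procedures. At λ = 0 the
solution matches ordinary least squares; at λ ≥ λ_max all penalized
coefficients are exactly zero; on orthonormal designs it equals
soft-thresholded OLS — all three are asserted in tests, alongside agreement
with an independent solver on general designs.

**Scaling.** Ordinal 1–4 responses are treated as numeric and z-scored
(population practice for CLPNs), so `B̂` holds standardized coefficients
(typical cross-lagged magnitudes ~0.02–0.1). Categorical covariates are
dummy-coded against their first level and centered but not scaled, keeping
their coefficients on the contrast scale.

## Centrality

With self-loops excluded (each index concerns a node's relation to the
*other* symptoms):

- `OEI(i) = Σ_{j≠i} B̂[i,j]` — out-expected influence,
- `IEI(j) = Σ_{i≠j} B̂[i,j]` — in-expected influence,
- `BEI(i) = Σ_{j: comm(j)≠comm(i)} B̂[i,j]` — bridge expected influence,
  outgoing cross-community edges only (an incoming variant exists for
  sensitivity analyses, as does an `include_autoregressive` flag).

Sums are signed. Two identities hold by construction and are enforced:
`Σ OEI = Σ IEI`, and `OEI = BEI + within-community out-sum` (computed with
that exact grouping so the identity is bitwise). Standardized centralities
z-score each index across the 16 nodes with the population SD (divide by n),
matching the usual centrality plots; standardization is monotone, so
rankings are unchanged. Raw and standardized values are both emitted because
published reports are not always explicit about which they show.

## Robustness

Both procedures resample **dyads** (the exchangeable unit) and re-run the
entire pipeline — standardization and CV penalty selection included — inside
every replicate, so uncertainty from model selection is part of the answer.
All replicate streams are seeded and bitwise reproducible.

- **Edge bootstrap**: nonparametric resampling with replacement (default
  1000 replicates); 95% percentile intervals whose endpoints are order
  statistics of the replicate set (so one replicate collapses to a point).
  Replicates whose resample has a constant column are skipped and logged;
  more than 10% skips aborts. Because the nodewise regressions are
  independent across outcome nodes, `bootstrap_edges(outcomes=...)` can
  restrict re-fitting to the outcome under study — exact for those columns,
  and the reason coverage simulations at n_boot = 500 stay cheap. Pairwise
  difference tests flag edge pairs (and node pairs, per centrality index)
  whose replicate-difference CI excludes zero. These percentile CIs describe
  sampling variability of a shrunken estimator; they are not significance
  tests for the population coefficient.
- **Correlation stability (CS)**: for each drop proportion p in
  {0.05, …, 0.75}, subsample ⌈(1−p)·n⌉ dyads without replacement
  (default 50 replicates per p), re-estimate, and correlate the raw index
  across the 16 nodes with the full-sample index. CS is the largest p at
  which ≥95% of subsamples correlate ≥0.70; below 0.25 the index is labeled
  unstable, 0.25–0.50 acceptable, ≥0.50 robust. Failed replicates (constant
  index, degenerate subsample) count against success; drop proportions whose
  subsample is smaller than the fold count are infeasible. Stored subsample
  correlations allow recomputing CS at any threshold, which is how the
  monotonicity property is tested.

## Network comparison

Two networks are matched node-by-node by (community, item) — B_D4 ↔ G_D4,
F_D7 ↔ M_D7 — then compared on: Pearson correlation of the vectorized 16×16
matrices (autoregressive diagonal included by default, covariate terms
never; the t-approximation p-value is reported with the caveat that edges
are not independent observations); the share of corresponding edges with the
same direction, where exact zero is its own class (LASSO zeros are exact);
per-index centrality correlations over the 16 matched nodes; and each
network's top-k (default 12) bridging edges ranked by signed weight with
lexicographic tie-breaks.

## Synthetic dyadic panels

Real two-wave family-panel microdata of this kind are access-restricted, so
the generator is a first-class module. It emulates the analysis model on a
latent scale: T1 latent severities are multivariate normal with exchangeable
correlations (0.3 within a person, 0.1 between parent and child); T2 is
`y₂ = Bᵀy₁ + Γᵀx + ε` with residuals sharing the same exchangeable
correlation pattern (without correlated residuals the wave-2 items would be
nearly independent cross-sectionally — internal consistency near zero —
which no real symptom scale shows; correlated residuals leave the nodewise
regression estimands untouched). Residual SDs are set so every T2 latent has
unit variance, making the standardized true coefficients equal `B_true`.
Each latent is discretized to 1–4 through three per-node cutpoints on the
unit-SD scale (monotone by construction); cutpoints are solved by bisection
so the ordinal means hit per-item targets in the 1.1–2.1 band typical of
general-population CES-D-8 samples (hopelessness rarest, ~1.1–1.2;
unhappiness most endorsed, ~1.8–2.1). The two positively-worded items are
emitted in raw (reflected) coding so the scoring step runs on realistic
input. Covariates (age, ethnicity, log-normal income, 4-level education) are
generated from simple parametric models and deleted MCAR at 5% per cell;
symptoms are always complete, because the study design excludes rather than
imputes symptom missingness. All randomness flows through one
`numpy.random.default_rng` (PCG64) seed.

The default population has 760 boy and 709 girl dyads (split ~evenly between
father and mother dyads), autoregressive effects of 0.3 on all 16 nodes, and
12 cross-lagged parent↔child effects of 0.05–0.15 — the magnitude band such
analyses report. What the generator does **not** emulate: attrition or
informative missingness, polychoric/ordinal measurement structure beyond
thresholding, family-level confounding (shared genes/environment beyond the
exchangeable correlation), and subgroup heterogeneity (all four dyad types
share one `B_true`). Passing tests therefore show the estimator recovers
the data-generating process it assumes, not that the assumptions hold in
any real population.

## Covariate imputation

Missing demographic covariates are filled with an iterative random-forest
scheme structured like missForest: mean/mode initialization, variables
visited in ascending-missingness order, each covariate regressed (100 trees)
on the other covariates plus all 32 symptom columns using originally
observed rows, stopping the first time the difference criterion rises (for
both variable types when both have holes) and returning the previous
iteration. Income is log-transformed for imputation; ethnicity and education
are treated as categorical. Observed cells are never modified and symptom
columns are never targets. Imputation runs once on the full retained panel
before subgroup splitting (a flag on the workflow could reorder this; with
MCAR holes the choice is immaterial).

## Numerical and design notes

- **Fold assignment** is a seeded uniform permutation, shared across the 16
  outcome regressions of one fit; every bootstrap/subsample replicate draws
  a fresh fold seed from its own seeded stream.
- **CV-min vs 1se**: under the CV-minimum rule a pure-noise regression
  retains a small number of tiny spurious coefficients (measured ~7% of
  entries at n≈1500, matching an independent LASSO-CV implementation);
  the 1se rule drives this to zero at the cost of shrinking true small
  effects. The default follows the common CV-minimum convention; sparsity
  consumers should prefer `lambda_rule="1se"`.
- **Discretization attenuation**: a latent cross-lagged coefficient of 0.4
  corresponds to ≈0.31 on the z-scored ordinal scale (computed by a
  large-sample OLS oracle); validation targets for ordinal-scale pipelines
  use the attenuated value.
- **Degenerate inputs**: zero-variance design columns raise a named error
  (and are the trigger for bootstrap replicate skipping); zero total-score
  variance makes Cronbach's α undefined (NaN + warning); zero-variance
  centrality indices yield missing z-scores; comparison of constant edge
  matrices yields missing correlations.
- **Problem sizes in the shipped tests**: sign recovery uses 10 populations
  of n = 5000 on the latent scale; bootstrap coverage uses 50 outer
  repetitions × 500 replicates at n = 2000 (single-outcome refits); CS
  simulations use 100 subsamples per drop proportion over 5 populations;
  the end-to-end determinism check runs a reduced robustness configuration.
  These sizes keep the full validation suite in the tens of minutes on one
  CPU while leaving every Monte Carlo margin interpretable.

## Known limitations

- Treating 1–4 ordinal items as numeric attenuates coefficients; no
  polychoric option is provided.
- Percentile bootstrap CIs around LASSO estimates do not attain nominal
  coverage for near-zero true effects (shrinkage bias); they are reported,
  as is conventional, for stability description.
- The Pearson p-values in network comparison treat 256 dependent edges as
  independent draws.
- Only two waves are supported; no contemporaneous (within-wave) network,
  no graphical-lasso partial correlations, no permutation-based network
  comparison test.
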