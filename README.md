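# clpnet

Cross-lagged panel network (CLPN) analysis of parent–adolescent
depressive-symptom transmission.

Depression runs in families, and network psychometrics asks *which symptoms
carry the transmission*: instead of relating two total scores, a CLPN
treats every CES-D-8 item of the child and of the parent as a node and
estimates the directed lagged effect of each wave-1 symptom on each wave-2
symptom. `clpnet` is for researchers working with two-wave dyadic panels
(parent–child pairs measured twice) who want the full workflow — scoring,
exclusions, covariate imputation, regularized network estimation,
centrality, stability diagnostics, and between-group comparison — as a
tested Python library. Because the family-panel microdata such studies use
are access-restricted, the package ships a synthetic dyadic-panel generator
with known cross-lagged structure, so every stage can be exercised and
validated end to end.

## The model

For z-scored item responses `y₁` (wave 1) and `y₂` (wave 2), each of the 16
wave-2 nodes is fit by a nodewise LASSO regression

    y₂ⱼ = Σᵢ B[i,j]·y₁ᵢ + Σₖ γ[k,j]·xₖ + ε,    minimize (1/2n)‖y−Xβ‖² + λΣ pfᵢ|βᵢ|

with demographic covariates `x` adjusted for but unpenalized, and λ chosen
per node by 10-fold cross-validation. The weight matrix `B̂` (row = source
at T1, column = target at T2) defines the directed network: the diagonal
holds autoregressive paths, and parent→child / child→parent entries are
*bridging edges* — the transmission pathways. Node importance is summarized
by signed expected-influence centralities (self-loops excluded):
out (OEI = Σⱼ B̂[i,j]), in (IEI = Σᵢ B̂[i,j]) and bridge
(BEI = outgoing cross-community sum). Robustness is quantified by
nonparametric bootstrap CIs on edges (full re-estimation per replicate) and
the case-dropping correlation-stability (CS) coefficient (≥0.25 acceptable,
≥0.50 robust); networks of different dyad types (boy–father, boy–mother,
girl–father, girl–mother) are compared by edge-matrix correlation,
direction agreement, centrality correlations and ranked bridging edges.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import clpnet as cn

panel, _, _ = cn.generate_dyads(cn.default_study_spec(seed=11))
panel = cn.apply_reverse_scoring(panel)       # D4/D6 are positively worded
panel, _ = cn.apply_exclusions(panel)         # drop incomplete/non-cohabiting
parts = cn.split_by_dyad_type(panel)

net = cn.fit_clpn(parts[("girl", "mother")], cn.FitConfig(fold_seed=13),
                  include_covariates=False)
cent = cn.standardize_centrality(cn.compute_centrality(net))
print(cent.table.round(3))
```

prints (abridged)

```
     community    oei    iei    bei  oei_z  iei_z  bei_z
G_D5     child  0.144 -0.069  0.130  1.061 -1.640  1.000
G_D8     child  0.156 -0.046  0.155  1.205 -1.346  1.288
M_D5    parent  0.276 -0.034  0.270  2.673 -1.184  2.612
M_D7    parent  0.036  0.220  0.036 -0.259  2.107 -0.085
...
```

Each `oei` entry is a sum of standardized lagged regression weights: the
girl's loneliness (G_D5) and hopelessness (G_D8) and the mother's
loneliness (M_D5) are the strongest *senders* in this simulated population
(high OEI/BEI — their wave-1 levels predict the other symptoms, including
the other family member's, at wave 2), while maternal sadness (M_D7) is
mainly a *receiver* (high IEI). The conservation identity
`Σ OEI = Σ IEI` (= 0.917 here) holds exactly by construction.

The `examples/` directory has one short script per capability: simulation
and descriptives, network fitting, centrality, bootstrap/CS robustness, and
network comparison. A thin CLI mirrors the workflow
(`clpn simulate | describe | impute | fit | centrality | bootstrap | cs |
compare | report | run-all`); `clpn run-all --config cfg.yaml` executes the
whole study from one seeded config and renders a Markdown report with
descriptives, per-network centrality and bridging-edge tables, CS verdicts
and all pairwise comparisons, fully determined by the config.

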