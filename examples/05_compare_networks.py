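"""Compare cross-lagged networks across dyad types.

Fits the four gender-specific networks (boy/girl x father/mother) and
compares boy-father vs girl-father: correlation of the full edge matrices,
share of edges with the same direction (+/-/exact zero), centrality
correlations, and each network's strongest bridging edges.
"""

import clpnet as cn

panel, _, _ = cn.generate_dyads(cn.default_study_spec(seed=11))
panel = cn.apply_reverse_scoring(panel)
panel, _ = cn.apply_exclusions(panel)
parts = cn.split_by_dyad_type(panel)

cfg = cn.FitConfig(fold_seed=13)
nets = {k: cn.fit_clpn(v, cfg, include_covariates=False)
        for k, v in parts.items()}

res = cn.compare_networks(nets[("boy", "father")], nets[("girl", "father")])
print("boy-father vs girl-father:")
print(f"  edge-matrix correlation r = {res.edge_corr:.3f} "
      f"(p = {res.edge_corr_p:.3f})")
print(f"  same-direction edges: {100 * res.prop_same_direction:.1f}% "
      f"({res.n_same}/{res.n_edges})")
for idx, d in res.centrality_corr.items():
    print(f"  {idx.upper()} correlation r = {d['r']:.2f} (p = {d['p']:.3f})")

print("\ntop bridging edges, boy-father (Measure / Edge Weight):")
print(res.top_edges_a.table.head(5).round(3).to_string(index=False))
print("\ntop bridging edges, girl-father:")
print(res.top_edges_b.table.head(5).round(3).to_string(index=False))
print("\nBoth networks are drawn from one synthetic population with shared")
print("cross-lagged structure, so edge correlations are positive and the")
print("same pathways top both bridging tables (unlike heterogeneous real")
print("subgroups, where near-zero correlations can occur).")
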