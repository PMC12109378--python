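"""Pairwise comparison of estimated cross-lagged networks.

Follows the usual intergroup-comparison recipe for lagged symptom networks:
correlate the vectorized edge matrices of the two networks (with a
two-sided t-approximation p-value), classify every corresponding edge pair
by direction (+ / − / exact zero — penalized estimates make zero a real
class) and report the fraction agreeing, correlate the raw centrality
indices node by node, and rank each network's strongest bridging edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import INDICES, compute_centrality
from .estimation import CLPNetwork, N_NODES
from .items import NodeId


class NodeMatchError(ValueError):
    pass


def match_nodes(net_a: CLPNetwork, net_b: CLPNetwork) -> list[tuple[NodeId, NodeId]]:
    """Correspondence between two networks' nodes by (community, item).

    Child roles (B/G) and parent roles (F/M) are aligned positionally, e.g.
    B_D4 <-> G_D4 and F_D7 <-> M_D7; within a network the item sets of both
    communities must match.
    """
    pairs = []
    for comm in ("child", "parent"):
        a_items = {n.item: n for n in net_a.nodes if n.community == comm}
        b_items = {n.item: n for n in net_b.nodes if n.community == comm}
        if set(a_items) != set(b_items):
            raise NodeMatchError(
                f"{comm} item sets differ: {sorted(a_items)} vs {sorted(b_items)}"
            )
        pairs += [(a_items[it], b_items[it]) for it in sorted(a_items)]
    return pairs


@dataclass
class BridgingEdgeTable:
    """Cross-community edges ranked by signed weight (descending)."""

    table: pd.DataFrame  # columns: source, target, weight

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["Measure"] = out["source"] + " → " + out["target"]
        out = out.rename(columns={"weight": "Edge Weight"})
        out[["Measure", "Edge Weight"]].to_csv(
            path, index=False, float_format="%.10g"
        )


@dataclass
class ComparisonResult:
    edge_corr: float
    edge_corr_p: float
    prop_same_direction: float
    prop_different_direction: float
    n_same: int
    n_edges: int
    centrality_corr: dict  # index -> {'r': float, 'p': float}
    top_edges_a: BridgingEdgeTable
    top_edges_b: BridgingEdgeTable

    def to_dict(self) -> dict:
        return {
            "edge_corr": self.edge_corr,
            "edge_corr_p": self.edge_corr_p,
            "prop_same_direction": self.prop_same_direction,
            "prop_different_direction": self.prop_different_direction,
            "n_same": self.n_same,
            "n_edges": self.n_edges,
            "centrality_corr": self.centrality_corr,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in a compared vector; r undefined", stacklevel=3)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_networks(
    net_a: CLPNetwork,
    net_b: CLPNetwork,
    include_autoregressive: bool = True,
    k_top: int = 12,
) -> ComparisonResult:
    """Global and local similarity of two networks.

    All 16x16 lagged coefficients (autoregressive diagonal included by
    default; covariate coefficients never) are vectorized in corresponding
    node order. The Pearson p-value treats edges as independent draws, which
    they are not — it is reported for comparability, not as a strict test.
    """
    pairs = match_nodes(net_a, net_b)
    ix_a = {str(n): i for i, n in enumerate(net_a.nodes)}
    ix_b = {str(n): i for i, n in enumerate(net_b.nodes)}
    order_a = np.array([ix_a[str(a)] for a, _ in pairs])
    order_b = np.array([ix_b[str(b)] for _, b in pairs])
    A = net_a.B_hat[np.ix_(order_a, order_a)]
    B = net_b.B_hat[np.ix_(order_b, order_b)]
    if not include_autoregressive:
        mask = ~np.eye(N_NODES, dtype=bool)
        va, vb = A[mask], B[mask]
    else:
        va, vb = A.ravel(), B.ravel()

    r, p = _pearson(va, vb)
    same = np.sign(va) == np.sign(vb)  # sign() maps exact zeros to their own class
    prop_same = float(same.mean())

    cent_a = compute_centrality(net_a).table.iloc[order_a]
    cent_b = compute_centrality(net_b).table.iloc[order_b]
    cc = {}
    for idx in INDICES:
        ri, pi = _pearson(
            cent_a[idx].to_numpy(float), cent_b[idx].to_numpy(float)
        )
        cc[idx] = {"r": ri, "p": pi}

    return ComparisonResult(
        edge_corr=r,
        edge_corr_p=p,
        prop_same_direction=prop_same,
        prop_different_direction=1.0 - prop_same,
        n_same=int(same.sum()),
        n_edges=int(same.size),
        centrality_corr=cc,
        top_edges_a=top_bridging_edges(net_a, k=k_top),
        top_edges_b=top_bridging_edges(net_b, k=k_top),
    )


def top_bridging_edges(net: CLPNetwork, k: int = 12) -> BridgingEdgeTable:
    """The k largest cross-community edges by signed weight.

    Ties break on (source, target) lexicographic order, so the ranking is
    deterministic. If fewer than k bridging edges exist, all are returned
    with a warning.
    """
    bridge = net.community_mask()
    names = net.node_names
    rows = [
        (names[i], names[j], float(net.B_hat[i, j]))
        for i in range(N_NODES)
        for j in range(N_NODES)
        if bridge[i, j]
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if k > len(rows):
        warnings.warn(
            f"requested top {k} bridging edges but only {len(rows)} exist",
            stacklevel=2,
        )
        k = len(rows)
    if all(w == 0.0 for _, _, w in rows):
        warnings.warn("all bridging edges are zero", stacklevel=2)
    return BridgingEdgeTable(
        pd.DataFrame(rows[:k], columns=["source", "target", "weight"])
    )
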