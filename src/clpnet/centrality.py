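"""Directed expected-influence centralities for cross-lagged networks.

For node i in a lagged network ``B`` (rows = T1 sources, cols = T2 targets):

    OEI(i) = Σ_{j≠i} B[i, j]        out-expected influence
    IEI(i) = Σ_{j≠i} B[j, i]        in-expected influence
    BEI(i) = Σ_{j: community(j) ≠ community(i)} B[i, j]

Sums are signed (negative edges subtract) and the autoregressive diagonal is
excluded — each index concerns a node's relation to the *other* symptoms.
BEI is built from outgoing edges only: it measures how strongly a symptom of
one family member transmits to the other member's symptoms one wave later.

Two exact identities follow from the definitions and are enforced in tests:
Σ OEI = Σ IEI (every off-diagonal edge counted once each way), and
OEI = BEI + within-community out-sum per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import CLPNetwork

INDICES = ("oei", "iei", "bei")


@dataclass
class CentralityTable:
    """Per-node OEI/IEI/BEI, raw and (once standardized) z-scored."""

    table: pd.DataFrame  # index: node name; columns: community, oei, iei, bei [+ _z]

    def __getitem__(self, index: str) -> pd.Series:
        return self.table[index]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="node", float_format="%.10g")


def compute_centrality(
    net: CLPNetwork, include_autoregressive: bool = False
) -> CentralityTable:
    """Signed expected-influence indices of every node.

    ``include_autoregressive=True`` adds the self-loop to OEI and IEI (a
    sensitivity option; the default follows the all-other-symptoms
    definition). BEI is structurally self-loop-free either way.
    """
    B = net.B_hat
    off = B if include_autoregressive else B - np.diag(np.diag(B))
    bridge = net.community_mask()
    bei = (B * bridge).sum(axis=1)
    # build OEI as bridge + within sums so the decomposition identity
    # oei = bei + within-out holds bitwise, not just to rounding
    within_out = (off * ~bridge).sum(axis=1)
    oei = bei + within_out
    iei = off.sum(axis=0)
    table = pd.DataFrame(
        {
            "community": [n.community for n in net.nodes],
            "oei": oei,
            "iei": iei,
            "bei": bei,
        },
        index=net.node_names,
    )
    return CentralityTable(table)


def incoming_bridge_ei(net: CLPNetwork) -> pd.Series:
    """Incoming-bridge variant: signed sum of cross-community edges INTO each
    node. Provided for sensitivity analyses; the default BEI is outgoing."""
    B = net.B_hat
    bridge = net.community_mask()
    return pd.Series((B * bridge).sum(axis=0), index=net.node_names, name="bei_in")


def standardize_centrality(cent: CentralityTable) -> CentralityTable:
    """Append z-scored columns (population SD across the 16 nodes).

    Standardization is a monotone transform, so node rankings are unchanged;
    a zero-variance index yields missing z-scores with a warning.
    """
    table = cent.table.copy()
    for idx in INDICES:
        v = table[idx].to_numpy(dtype=float)
        sd = v.std()  # population SD, matching common centrality plots
        if sd == 0:
            warnings.warn(f"{idx} has zero variance; z-scores undefined", stacklevel=2)
            table[idx + "_z"] = np.nan
        else:
            table[idx + "_z"] = (v - v.mean()) / sd
    return CentralityTable(table)
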