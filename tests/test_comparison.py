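"""Network comparison: identities, hand-computed toys, bridging-edge tables."""

import numpy as np
import pandas as pd
import pytest

from clpnet.comparison import (
    NodeMatchError,
    compare_networks,
    match_nodes,
    top_bridging_edges,
)
from clpnet.estimation import CLPNetwork, FitConfig, fit_clpn
from clpnet.items import ITEM_CODES, NodeId, node_ids

from conftest import make_panel, random_network


def _net(B, child="boy", parent="father"):
    return CLPNetwork(
        nodes=node_ids(child, parent),
        B_hat=B,
        lambda_per_node=np.zeros(16),
        covariate_coefs=pd.DataFrame(),
        n_used=100,
        config=FitConfig(),
    )


class TestMatchNodes:
    def test_aligns_child_roles_positionally(self):
        rng = np.random.default_rng(0)
        bf = _net(rng.normal(size=(16, 16)), "boy", "father")
        gf = _net(rng.normal(size=(16, 16)), "girl", "father")
        pairs = dict(
            (str(a), str(b)) for a, b in match_nodes(bf, gf)
        )
        assert pairs["B_D4"] == "G_D4" and pairs["F_D7"] == "F_D7"

    def test_aligns_parent_roles_positionally(self):
        rng = np.random.default_rng(1)
        bf = _net(rng.normal(size=(16, 16)), "boy", "father")
        bm = _net(rng.normal(size=(16, 16)), "boy", "mother")
        pairs = dict((str(a), str(b)) for a, b in match_nodes(bf, bm))
        assert pairs["F_D7"] == "M_D7" and pairs["B_D1"] == "B_D1"

    def test_mismatched_item_sets_error(self):
        rng = np.random.default_rng(2)
        good = _net(rng.normal(size=(16, 16)))
        broken = _net(rng.normal(size=(16, 16)))
        broken.nodes = [NodeId("B", "D1")] * 8 + [
            NodeId("F", i) for i in ITEM_CODES
        ]
        with pytest.raises(NodeMatchError, match="item sets differ"):
            match_nodes(good, broken)


class TestCompareNetworks:
    def test_self_comparison_identity(self, fitted_network):
        res = compare_networks(fitted_network, fitted_network)
        assert res.edge_corr == pytest.approx(1.0, abs=1e-12)
        assert res.prop_same_direction == 1.0
        for d in res.centrality_corr.values():
            assert d["r"] == pytest.approx(1.0, abs=1e-12)

    def test_negation_flips_everything_when_no_zero_edges(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(16, 16))
        B[B == 0] = 0.1
        a, b = _net(B), _net(-B)
        res = compare_networks(a, b)
        assert res.edge_corr == pytest.approx(-1.0, abs=1e-12)
        assert res.prop_same_direction == 0.0

    def test_three_edge_toy_direction_classes_and_correlation(self):
        # A = (0.2, 0, -0.1) vs B = (0.1, 0.3, -0.2) in three cells, zeros
        # elsewhere: classes (+,0,-) vs (+,+,-) -> 2 of the 3 touched cells
        # agree, all 253 untouched cells agree as (0,0)
        A, B = np.zeros((16, 16)), np.zeros((16, 16))
        cells = [(0, 8), (1, 9), (2, 10)]
        for (i, j), a, b in zip(cells, (0.2, 0.0, -0.1), (0.1, 0.3, -0.2)):
            A[i, j], B[i, j] = a, b
        res = compare_networks(_net(A), _net(B))
        assert res.n_same == 253 + 2
        assert res.prop_same_direction == pytest.approx(255 / 256)
        # independent correlation oracle from explicit sums
        va, vb = A.ravel(), B.ravel()
        n = va.size
        num = (va * vb).sum() - va.sum() * vb.sum() / n
        den = np.sqrt(
            ((va**2).sum() - va.sum() ** 2 / n)
            * ((vb**2).sum() - vb.sum() ** 2 / n)
        )
        assert res.edge_corr == pytest.approx(num / den, abs=1e-12)

    def test_direction_share_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(4)
        a = random_network(rng)
        scaled = _net(2.5 * a.B_hat)
        r1 = compare_networks(a, scaled)
        assert r1.prop_same_direction == 1.0

    def test_prop_same_plus_prop_different_is_one(self, fitted_network):
        rng = np.random.default_rng(5)
        other = random_network(rng)
        res = compare_networks(fitted_network, other)
        assert res.prop_same_direction + res.prop_different_direction == 1.0

    def test_zero_variance_edge_matrix_yields_missing_r(self):
        a = _net(np.zeros((16, 16)))
        b = _net(np.zeros((16, 16)))
        with pytest.warns(UserWarning, match="zero variance"):
            res = compare_networks(a, b)
        assert np.isnan(res.edge_corr)

    def test_fitted_subgroups_from_one_population_agree(self):
        # two halves of one homogeneous sample: positive edge correlation
        panel = make_panel(400, seed=30)
        half1 = panel.df.iloc[:200].reset_index(drop=True)
        half2 = panel.df.iloc[200:].reset_index(drop=True)
        from clpnet.panel import DyadPanel

        cfg = FitConfig(fold_seed=6, n_lambda=30)
        n1 = fit_clpn(DyadPanel(half1, dict(panel.metadata)), cfg,
                      include_covariates=False)
        n2 = fit_clpn(DyadPanel(half2, dict(panel.metadata)), cfg,
                      include_covariates=False)
        res = compare_networks(n1, n2)
        assert np.isfinite(res.edge_corr)
        assert 0 <= res.edge_corr_p <= 1


class TestTopBridgingEdges:
    def test_toy_ranking(self):
        B = np.zeros((16, 16))
        np.fill_diagonal(B, 0.5)
        B[0, 8], B[0, 1], B[8, 0] = 0.2, 0.1, -0.1
        table = top_bridging_edges(_net(B), k=3).table
        assert list(table.iloc[0]) == ["B_D1", "F_D1", 0.2]
        # signed ranking: zero bridge edges outrank the negative one
        assert (table.iloc[1:]["weight"] == 0.0).all()
        assert (np.diff(table["weight"]) <= 0).all()
        full = top_bridging_edges(_net(B), k=128).table
        assert list(full.iloc[-1][["source", "target"]]) == ["F_D1", "B_D1"]
        assert full.iloc[-1]["weight"] == -0.1

    def test_only_cross_community_edges_appear(self, fitted_network):
        table = top_bridging_edges(fitted_network).table
        for _, row in table.iterrows():
            src, dst = NodeId.parse(row.source), NodeId.parse(row.target)
            assert src.community != dst.community

    def test_ties_break_lexicographically(self):
        B = np.zeros((16, 16))
        B[1, 8] = B[0, 8] = B[0, 9] = 0.2
        table = top_bridging_edges(_net(B), k=3).table
        assert list(zip(table.source, table.target)) == [
            ("B_D1", "F_D1"), ("B_D1", "F_D2"), ("B_D2", "F_D1")
        ]

    def test_requesting_more_than_available_warns_and_returns_all(self):
        rng = np.random.default_rng(6)
        net = random_network(rng)
        with pytest.warns(UserWarning, match="only 128"):
            table = top_bridging_edges(net, k=200).table
        assert len(table) == 128

    def test_all_zero_bridge_block_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            table = top_bridging_edges(_net(np.zeros((16, 16))), k=5).table
        assert (table.weight == 0).all()

    def test_export_uses_published_table_headers(self, fitted_network, tmp_path):
        path = tmp_path / "bridging.csv"
        top_bridging_edges(fitted_network).to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "Measure,Edge Weight"
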