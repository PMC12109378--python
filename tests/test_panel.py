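"""Data model: I/O round-trips, scoring, exclusions, splits, descriptives."""

import numpy as np
import pandas as pd
import pytest

from clpnet.items import NodeId
from clpnet.panel import (
    DyadPanel,
    PanelConfigError,
    PanelValidationError,
    ScoringStateError,
    apply_exclusions,
    apply_reverse_scoring,
    cronbach_alpha,
    describe,
    read_panel,
    role_coded_column_map,
    split_by_dyad_type,
    write_panel,
)

from conftest import make_panel, make_panel_df


class TestNodeId:
    def test_renders_in_published_edge_notation(self):
        assert str(NodeId("F", "D7")) == "F_D7"
        assert NodeId.parse("B_D4") == NodeId("B", "D4")

    @pytest.mark.parametrize("role,item", [("X", "D1"), ("F", "D9"), ("f", "D1")])
    def test_rejects_unknown_role_or_item(self, role, item):
        with pytest.raises(ValueError):
            NodeId(role, item)

    def test_community_split(self):
        assert NodeId("B", "D1").community == "child"
        assert NodeId("G", "D1").community == "child"
        assert NodeId("M", "D8").community == "parent"


class TestReverseScoring:
    @pytest.mark.parametrize(
        "item,raw,expected",
        [("D4", 4, 1), ("D4", 2, 3), ("D6", 1, 4), ("D1", 3, 3), ("D7", 2, 2)],
    )
    def test_reversal_rule(self, item, raw, expected):
        panel = make_panel(1, seed=0)
        panel.metadata["scored"] = False
        panel.df[f"C_{item}_T1"] = float(raw)
        scored = apply_reverse_scoring(panel)
        assert scored.df[f"C_{item}_T1"].iloc[0] == expected

    def test_double_application_is_a_state_error(self):
        panel = make_panel(3, seed=1)
        panel.metadata["scored"] = False
        scored = apply_reverse_scoring(panel)
        with pytest.raises(ScoringStateError):
            apply_reverse_scoring(scored)

    def test_record_level_scoring_and_refusal(self):
        panel = make_panel(1, seed=2)
        panel.metadata["scored"] = False
        rec = next(panel.records())
        scored = rec.apply_reverse_scoring()
        assert scored.child_items_T1[3] == 5 - rec.child_items_T1[3]  # D4
        assert scored.child_items_T1[0] == rec.child_items_T1[0]  # D1
        with pytest.raises(ScoringStateError):
            scored.apply_reverse_scoring()

    def test_scored_means_mirror_raw_means(self):
        raw = make_panel(200, seed=3)
        raw.metadata["scored"] = False
        scored = apply_reverse_scoring(raw)
        m_raw = raw.df["P_D4_T2"].mean()
        m_scored = scored.df["P_D4_T2"].mean()
        assert m_scored == pytest.approx(5 - m_raw, abs=1e-12)


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        panel = make_panel(3, seed=4)
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        back = read_panel(path, scored=True)
        pd.testing.assert_frame_equal(back.df, panel.df[back.df.columns])

    def test_role_coded_round_trip(self, tmp_path):
        panel = make_panel(5, seed=5, child_gender="girl", parent_role="mother")
        path = tmp_path / "panel.csv"
        write_panel(panel, path, role_coded=True)
        header = path.read_text().splitlines()[0]
        assert "G_D4_T1" in header and "M_D7_T2" in header
        back = read_panel(
            path, column_map=role_coded_column_map("girl", "mother"), scored=True
        )
        pd.testing.assert_frame_equal(back.df, panel.df[back.df.columns])

    def test_out_of_range_symptom_names_row_and_column(self, tmp_path):
        df = make_panel_df(3, np.random.default_rng(6))
        df.loc[1, "C_D2_T1"] = 5
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="C_D2_T1.*row 1"):
            read_panel(path)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        df = make_panel_df(3, np.random.default_rng(7)).drop(columns=["child_gender"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelConfigError, match="child_gender"):
            read_panel(path)

    def test_empty_and_na_cells_are_missing(self, tmp_path):
        df = make_panel_df(2, np.random.default_rng(8))
        df["C_D1_T1"] = df["C_D1_T1"].astype(object)
        df.loc[0, "C_D1_T1"] = ""
        df.loc[1, "annual_family_income"] = "NA"
        path = tmp_path / "na.csv"
        df.to_csv(path, index=False)
        back = read_panel(path)
        assert np.isnan(back.df.loc[0, "C_D1_T1"])
        assert np.isnan(back.df.loc[1, "annual_family_income"])


class TestExclusions:
    def test_hand_traced_rules_and_attribution_order(self):
        df = make_panel_df(5, np.random.default_rng(9))
        df.loc[1, "C_D3_T1"] = np.nan  # missing child item
        df.loc[2, "P_D7_T2"] = np.nan  # missing parent item
        df.loc[3, "cohabiting_T2"] = False
        panel = DyadPanel(df, {"scored": True})
        kept, log = apply_exclusions(panel)
        assert list(kept.df["dyad_id"]) == ["t00000", "t00004"]
        assert log.missing_symptoms == 2 and log.not_cohabiting == 1

    def test_missingness_counted_before_cohabitation(self):
        df = make_panel_df(1, np.random.default_rng(10))
        df.loc[0, "C_D1_T1"] = np.nan
        df.loc[0, "cohabiting_T1"] = False  # trips both rules
        _, log = apply_exclusions(DyadPanel(df, {"scored": True}))
        assert log.missing_symptoms == 1 and log.not_cohabiting == 0

    def test_complete_panel_unchanged_with_empty_log(self):
        panel = make_panel(10, seed=11)
        kept, log = apply_exclusions(panel)
        assert len(kept) == 10
        assert log.missing_symptoms == 0 and log.not_cohabiting == 0

    def test_size_conservation(self):
        rng = np.random.default_rng(12)
        df = make_panel_df(50, rng)
        for i in rng.choice(50, 12, replace=False):
            df.loc[i, rng.choice(list(df.columns[5:37]))] = np.nan
        for i in rng.choice(50, 8, replace=False):
            df.loc[i, "cohabiting_T1"] = False
        kept, log = apply_exclusions(DyadPanel(df, {"scored": True}))
        assert len(kept) + log.missing_symptoms + log.not_cohabiting == 50


class TestSplit:
    def test_partition_is_a_disjoint_cover(self):
        panel = make_panel(40, seed=13, child_gender=None, parent_role=None)
        parts = split_by_dyad_type(panel)
        sizes = sum(len(p) for p in parts.values())
        assert sizes == len(panel)
        ids = pd.concat([p.df["dyad_id"] for p in parts.values()])
        assert ids.is_unique and set(ids) == set(panel.df["dyad_id"])
        for (g, r), p in parts.items():
            assert (p.df["child_gender"] == g).all()
            assert (p.df["parent_role"] == r).all()

    def test_empty_part_warns(self):
        panel = make_panel(5, seed=14, child_gender="boy", parent_role="father")
        with pytest.warns(UserWarning, match="girl-father"):
            parts = split_by_dyad_type(panel)
        assert len(parts[("girl", "father")]) == 0


class TestDescriptives:
    def test_alpha_is_one_for_perfectly_consistent_responses(self):
        # each person answers every item identically; persons differ
        scores = np.repeat(np.array([1.0, 2, 3, 4, 2, 3])[:, None], 8, axis=1)
        assert cronbach_alpha(scores) == pytest.approx(1.0, abs=1e-12)

    def test_alpha_matches_closed_form_on_constructed_covariance(self):
        # exact sample covariance [[1, .5], [.5, 1]] -> alpha = 2*(1-2/3) = 2/3
        rng = np.random.default_rng(15)
        M = rng.standard_normal((40, 2))
        M -= M.mean(axis=0)
        S = np.cov(M, rowvar=False)
        target = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = M @ np.linalg.inv(np.linalg.cholesky(S)).T @ np.linalg.cholesky(target).T
        assert cronbach_alpha(M) == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_alpha_undefined_for_zero_total_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            a = cronbach_alpha(np.ones((5, 3)))
        assert np.isnan(a)

    def test_item_mean_and_sd(self):
        panel = make_panel(4, seed=16)
        panel.df["C_D1_T1"] = [1.0, 2.0, 3.0, 4.0]
        table = describe(panel).table
        row = table.query("item == 'D1' and member == 'child' and wave == 'T1'")
        assert row["mean"].iloc[0] == pytest.approx(2.5)
        assert row["sd"].iloc[0] == pytest.approx(np.sqrt(5.0 / 3.0), abs=1e-9)
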