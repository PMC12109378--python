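"""Shared fixtures: programmatically built panels and networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clpnet.items import ITEM_CODES, node_ids
from clpnet.estimation import CLPNetwork, FitConfig
from clpnet.panel import ALL_COLUMNS, DyadPanel, SYMPTOM_COLUMNS


def make_panel_df(
    n: int,
    rng: np.random.Generator,
    child_gender: str | None = "boy",
    parent_role: str | None = "father",
) -> pd.DataFrame:
    """A fully observed, cohabiting, valid panel frame with random responses."""
    genders = (
        [child_gender] * n
        if child_gender
        else list(rng.choice(["boy", "girl"], size=n))
    )
    roles = (
        [parent_role] * n
        if parent_role
        else list(rng.choice(["father", "mother"], size=n))
    )
    data = {
        "dyad_id": [f"t{i:05d}" for i in range(n)],
        "child_gender": genders,
        "parent_role": roles,
        "cohabiting_T1": [True] * n,
        "cohabiting_T2": [True] * n,
        "child_age": rng.uniform(9, 16, n).round(1),
        "ethnicity": rng.choice([1.0, 2.0], size=n, p=[0.85, 0.15]),
        "annual_family_income": rng.lognormal(11, 0.8, n).round(0),
        "parent_education": rng.choice([1.0, 2.0, 3.0, 4.0], size=n),
    }
    for col in SYMPTOM_COLUMNS:
        data[col] = rng.integers(1, 5, n).astype(float)
    return pd.DataFrame(data)[list(ALL_COLUMNS)]


def make_panel(n: int, seed: int = 0, **kw) -> DyadPanel:
    df = make_panel_df(n, np.random.default_rng(seed), **kw)
    return DyadPanel(df, {"provenance": "test fixture", "scored": True})


def random_network(rng: np.random.Generator, sparsity: float = 0.5) -> CLPNetwork:
    """A random 16-node network with exact zeros, for property tests."""
    B = rng.normal(0, 0.1, (16, 16))
    B[rng.random((16, 16)) < sparsity] = 0.0
    np.fill_diagonal(B, rng.uniform(0.1, 0.4, 16))
    return CLPNetwork(
        nodes=node_ids("boy", "father"),
        B_hat=B,
        lambda_per_node=np.full(16, 0.05),
        covariate_coefs=pd.DataFrame(index=[], columns=[f"B_{i}" for i in ITEM_CODES]),
        n_used=100,
        config=FitConfig(),
    )


@pytest.fixture(scope="session")
def analysis_panel() -> DyadPanel:
    """A mid-sized single-dyad-type panel, scored, ready for estimation."""
    return make_panel(400, seed=42)


@pytest.fixture(scope="session")
def fitted_network(analysis_panel) -> CLPNetwork:
    from clpnet.estimation import fit_clpn

    return fit_clpn(
        analysis_panel, FitConfig(fold_seed=7), include_covariates=False
    )
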