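"""Iterative random-forest imputation of demographic covariates.

Structure follows the missForest algorithm: initialize missing cells with
the column mean (continuous) or mode (categorical), then repeatedly loop
over the covariates in ascending-missingness order, fitting a random forest
of each covariate on all other covariates plus the 32 symptom columns using
the originally-observed rows and predicting the originally-missing cells.
Iteration stops the first time the difference criterion increases (for both
variable types, when both have missing cells), and the previous iteration's
values are returned.

Only covariates are ever imputed: symptom responses are complete by this
stage (dyads with missing responses are excluded, not imputed) and serve
purely as predictors. Annual family income is log-transformed for imputation
and back-transformed afterwards. The random forests are scikit-learn's;
the iteration and stopping logic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .panel import CATEGORICAL_COVARIATES, COVARIATES, DyadPanel, SYMPTOM_COLUMNS

CONTINUOUS_COVARIATES = tuple(c for c in COVARIATES if c not in CATEGORICAL_COVARIATES)
LOG_TRANSFORMED = ("annual_family_income",)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationConfig:
    n_trees: int = 100
    max_iter: int = 10
    seed: int = 0
    variables: tuple = COVARIATES  # imputation targets; ordered by missingness at run time

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_iter < 1:
            raise ValueError("n_trees and max_iter must be >= 1")
        unknown = set(self.variables) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass
class ImputationReport:
    iterations: int = 0
    diff_continuous: list = field(default_factory=list)
    diff_categorical: list = field(default_factory=list)
    converged: bool = False
    n_missing: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "diff_continuous": self.diff_continuous,
            "diff_categorical": self.diff_categorical,
            "converged": self.converged,
            "n_missing": self.n_missing,
        }


def impute_covariates(
    panel: DyadPanel, config: ImputationConfig | None = None
) -> tuple[DyadPanel, ImputationReport]:
    """Fill every missing covariate cell; observed cells are never altered."""
    config = config or ImputationConfig()
    df = panel.df
    if df[list(SYMPTOM_COLUMNS)].isna().any().any():
        raise ImputationError(
            "symptom columns contain missing values; apply exclusions first"
        )
    targets = [v for v in COVARIATES if v in config.variables]
    masks = {v: df[v].isna().to_numpy() for v in targets}
    report = ImputationReport(
        n_missing={v: int(m.sum()) for v, m in masks.items()}
    )
    for v, m in masks.items():
        if m.all() and len(df) > 0:
            raise ImputationError(
                f"covariate {v!r} is entirely missing; drop it from "
                "ImputationConfig.variables or supply values"
            )
    if not any(m.any() for m in masks.values()):
        report.iterations = 1
        report.converged = True
        return panel.copy(), report

    # working matrix on the imputation scale
    work = df[list(COVARIATES)].astype(float).copy()
    for v in LOG_TRANSFORMED:
        work[v] = np.log(work[v])
    cont = [v for v in targets if v in CONTINUOUS_COVARIATES and masks[v].any()]
    cat = [v for v in targets if v in CATEGORICAL_COVARIATES and masks[v].any()]

    # initialization: column mean / mode over observed cells
    for v in targets:
        obs = work[v].dropna()
        if v in CATEGORICAL_COVARIATES:
            fill = obs.mode().iloc[0]
        else:
            fill = obs.mean()
        work.loc[masks[v], v] = fill

    order = sorted(
        [v for v in targets if masks[v].any()], key=lambda v: masks[v].sum()
    )
    symptoms = df[list(SYMPTOM_COLUMNS)].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)

    prev = work.copy()
    best = work.copy()
    prev_dc = prev_dk = np.inf
    for it in range(1, config.max_iter + 1):
        for v in order:
            others = [c for c in COVARIATES if c != v]
            X = np.column_stack([work[others].to_numpy(dtype=float), symptoms])
            y = work[v].to_numpy(dtype=float)
            obs = ~masks[v]
            rs = int(rng.integers(0, 2**31 - 1))
            if v in CATEGORICAL_COVARIATES:
                model = RandomForestClassifier(
                    n_estimators=config.n_trees, random_state=rs, n_jobs=1
                )
                model.fit(X[obs], y[obs].astype(int))
                work.loc[masks[v], v] = model.predict(X[masks[v]]).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=config.n_trees, random_state=rs, n_jobs=1
                )
                model.fit(X[obs], y[obs])
                work.loc[masks[v], v] = model.predict(X[masks[v]])

        dc = dk = 0.0
        if cont:
            num = sum(
                float(((work[v] - prev[v]) ** 2).sum()) for v in cont
            )
            den = sum(float((work[v] ** 2).sum()) for v in cont)
            dc = num / den if den > 0 else 0.0
        if cat:
            changed = sum(
                int((work.loc[masks[v], v] != prev.loc[masks[v], v]).sum())
                for v in cat
            )
            total = sum(int(masks[v].sum()) for v in cat)
            dk = changed / total
        report.iterations = it
        report.diff_continuous.append(dc)
        report.diff_categorical.append(dk)

        inc_c = (dc > prev_dc) if cont else True
        inc_k = (dk > prev_dk) if cat else True
        if it > 1 and inc_c and inc_k:
            report.converged = True
            work = best  # criterion rose: keep the previous iteration
            break
        best = work.copy()
        prev = work.copy()
        prev_dc, prev_dk = dc, dk

    out = panel.copy()
    filled = work.copy()
    for v in LOG_TRANSFORMED:
        filled[v] = np.exp(filled[v])
    for v in targets:
        col = out.df[v].to_numpy(dtype=float)
        col[masks[v]] = filled.loc[masks[v], v].to_numpy(dtype=float)
        out.df[v] = col
    return out, report
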