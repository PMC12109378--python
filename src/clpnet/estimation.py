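"""Cross-lagged panel network estimation via penalized nodewise regression.

Each of the 16 symptom variables at wave 2 is regressed on all 16 symptom
variables at wave 1 plus the demographic covariates, with an L1 penalty on
the symptom predictors (covariates are adjusted for but unpenalized by
default, and are not network nodes). The penalty for each outcome node is
chosen by K-fold cross-validation over a log-spaced grid; folds are drawn
once from ``fold_seed`` and shared across the 16 nodewise regressions so a
fit is fully determined by (data, config).

Ordinal 1-4 responses are treated as numeric and z-scored, so the resulting
weight matrix ``B_hat`` holds standardized lagged regression coefficients:
``B_hat[i, j]`` is the effect of node i at T1 on node j at T2 (the diagonal
holds the autoregressive paths).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._cd import cd_gram, path_gram
from .items import ITEM_CODES, NodeId, node_ids
from .panel import CATEGORICAL_COVARIATES, COVARIATES, DyadPanel, ScoringStateError

N_NODES = 16


class ZeroVarianceError(ValueError):
    """A design column has zero variance and cannot be standardized."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Settings of the nodewise penalized regressions."""

    n_folds: int = 10
    lambda_rule: str = "min"  # 'min' or '1se'
    penalize_covariates: bool = False
    standardize: bool = True
    fold_seed: int = 0
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-7
    max_sweeps: int = 100_000

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in {"min", "1se"}:
            raise ValueError("lambda_rule must be 'min' or '1se'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScalingRecord:
    """Standardization constants; allows mapping coefficients back."""

    names: list
    mean: np.ndarray
    scale: np.ndarray  # 1.0 for dummy columns (centered, not scaled)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.mean


@dataclass
class DesignMatrices:
    """Standardized design: T1/T2 symptom blocks and covariate block."""

    Y1: np.ndarray  # (n, 16) z-scored T1 symptoms
    Y2: np.ndarray  # (n, 16) z-scored T2 symptoms
    X_cov: np.ndarray  # (n, k) centered covariate columns (may be k=0)
    node_labels: list  # generic C_/P_ labels, child block first
    cov_labels: list
    scaling: dict  # block name -> ScalingRecord


def _zscore(
    block: np.ndarray, names: list, scale: bool = True
) -> tuple[np.ndarray, ScalingRecord]:
    mean = block.mean(axis=0)
    sd = block.std(axis=0)
    zero = np.flatnonzero(sd <= 0.0)
    if zero.size:
        raise ZeroVarianceError(f"zero-variance column(s): {[names[i] for i in zero]}")
    s = sd if scale else np.ones_like(sd)
    return (block - mean) / s, ScalingRecord(list(names), mean, s)


def standardize_panel(
    panel: DyadPanel, include_covariates: bool = True, scale: bool = True
) -> DesignMatrices:
    """Build centered/scaled design matrices from an analysis-ready panel.

    Symptom columns and continuous covariates are z-scored; categorical
    covariates are dummy-coded against their first level and centered (scale
    kept at 1 so the dummy coefficient stays on the 0/1 contrast scale).
    Raises :class:`ZeroVarianceError` naming any constant column.
    """
    node_labels = [f"C_{it}" for it in ITEM_CODES] + [f"P_{it}" for it in ITEM_CODES]
    y1 = panel.symptom_values(wave="T1")
    y2 = panel.symptom_values(wave="T2")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise ValueError("symptom responses contain missing values; apply exclusions")
    Y1, s1 = _zscore(y1, [f"{n}_T1" for n in node_labels], scale=scale)
    Y2, s2 = _zscore(y2, [f"{n}_T2" for n in node_labels], scale=scale)

    cov_cols, cov_names = [], []
    if include_covariates:
        for name in COVARIATES:
            col = panel.df[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(
                    f"covariate {name!r} has missing values; impute covariates first"
                )
            if name in CATEGORICAL_COVARIATES:
                levels = np.unique(col)
                for lev in levels[1:]:  # first level is the reference
                    cov_cols.append((col == lev).astype(float))
                    cov_names.append(f"{name}_{int(lev)}")
            else:
                cov_cols.append(col)
                cov_names.append(name)
    if cov_cols:
        X = np.column_stack(cov_cols)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ZeroVarianceError(
                f"zero-variance column(s): {[cov_names[i] for i in zero]}"
            )
        scale = np.where(
            [n.rsplit("_", 1)[0] in CATEGORICAL_COVARIATES for n in cov_names], 1.0, sd
        )
        Xc = (X - mean) / scale
        s_cov = ScalingRecord(list(cov_names), mean, scale)
    else:
        Xc = np.empty((len(panel.df), 0))
        s_cov = ScalingRecord([], np.empty(0), np.empty(0))
    return DesignMatrices(
        Y1=Y1,
        Y2=Y2,
        X_cov=Xc,
        node_labels=node_labels,
        cov_labels=cov_names,
        scaling={"T1": s1, "T2": s2, "covariates": s_cov},
    )


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

def lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    penalty_factors: np.ndarray | None = None,
    lam: float = 0.0,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Solve ``min (1/(2n))‖y − Xβ‖² + λ Σ pf_j |β_j|`` by cyclic coordinate
    descent with soft-thresholding. Deterministic given its inputs."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    G = X.T @ X / n
    c = X.T @ y / n
    beta = np.zeros(p)
    sweeps = cd_gram(G, c, float(lam), pf, beta, max_sweeps, tol)
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(lambda={lam}, p={p}, n={n})"
        )
    return beta


def lambda_grid_max(G: np.ndarray, c: np.ndarray, pf: np.ndarray) -> float:
    """Smallest λ at which every penalized coefficient is zero.

    With unpenalized columns present, the penalized columns' correlations are
    taken against the residual from the unpenalized-only least-squares fit.
    """
    pen = pf > 0
    if pen.all():
        lmax = float(np.max(np.abs(c[pen]))) if pen.any() else 0.0
    else:
        u = ~pen
        beta_u = np.linalg.solve(G[np.ix_(u, u)], c[u])
        resid_corr = c[pen] - G[np.ix_(pen, u)] @ beta_u
        lmax = float(np.max(np.abs(resid_corr))) if pen.any() else 0.0
    return max(lmax, 1e-6)


def _make_grid(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _fold_ids(n: int, n_folds: int, fold_seed: int) -> np.ndarray:
    perm = np.random.default_rng(fold_seed).permutation(n)
    ids = np.empty(n, dtype=np.int64)
    ids[perm] = np.arange(n) % n_folds
    return ids


def cv_lasso_multi(
    X: np.ndarray,
    Y: np.ndarray,
    pf: np.ndarray,
    config: FitConfig,
    outcomes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Cross-validated nodewise LASSO for several outcome columns at once.

    All outcomes share the predictor matrix and the CV folds; each outcome
    gets its own λ grid (anchored at its λ_max) and chosen penalty. Returns
    ``(coefs, lambdas, cv_curves)`` with ``coefs[:, j]`` the full-data refit
    at the chosen λ for outcome j (NaN columns for outcomes not requested).
    """
    n, p = X.shape
    m = Y.shape[1]
    if n < config.n_folds:
        raise ValueError(f"n={n} is smaller than n_folds={config.n_folds}")
    which = np.arange(m) if outcomes is None else np.asarray(outcomes, dtype=int)
    pf = np.asarray(pf, dtype=float)

    G_full = X.T @ X / n
    C_full = X.T @ Y / n
    ids = _fold_ids(n, config.n_folds, config.fold_seed)

    folds = []
    for f in range(config.n_folds):
        val = ids == f
        Xtr, Xva = X[~val], X[val]
        ntr = len(Xtr)
        folds.append(
            {
                "G": Xtr.T @ Xtr / ntr,
                "C": Xtr.T @ Y[~val] / ntr,
                "Xva": Xva,
                "Yva": Y[val],
            }
        )

    coefs = np.full((p, m), np.nan)
    lambdas = np.full(m, np.nan)
    curves: list = [None] * m
    for j in which:
        lmax = lambda_grid_max(G_full, C_full[:, j], pf)
        grid = _make_grid(lmax, config.n_lambda, config.lambda_min_ratio)
        mse = np.zeros((config.n_folds, len(grid)))
        for f, fd in enumerate(folds):
            betas, fail = path_gram(
                fd["G"], fd["C"][:, j], grid, pf, config.tol, config.max_sweeps
            )
            if fail >= 0:
                raise ConvergenceError(
                    f"CV path failed to converge (outcome {j}, fold {f}, "
                    f"lambda={grid[fail]:.3g})"
                )
            resid = fd["Yva"][:, [j]] - fd["Xva"] @ betas.T
            mse[f] = (resid**2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        if not np.isfinite(mean_mse).all():
            raise ConvergenceError(f"non-finite CV curve for outcome {j}")
        i_min = int(np.argmin(mean_mse))
        if config.lambda_rule == "1se":
            se = mse.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
            ok = mean_mse <= mean_mse[i_min] + se[i_min]
            i_sel = int(np.flatnonzero(ok)[0])  # grid descends: largest λ first
        else:
            i_sel = i_min
        betas, fail = path_gram(
            G_full, C_full[:, j], grid[: i_sel + 1], pf, config.tol, config.max_sweeps
        )
        if fail >= 0:
            raise ConvergenceError(f"full-data refit failed (outcome {j})")
        coefs[:, j] = betas[i_sel]
        lambdas[j] = grid[i_sel]
        curves[j] = {"lambda": grid, "cv_mse": mean_mse}
    return coefs, lambdas, curves


# ---------------------------------------------------------------------------
# Network container and fitting
# ---------------------------------------------------------------------------

@dataclass
class CLPNetwork:
    """A 16-node directed lagged network.

    ``B_hat[i, j]`` is the standardized coefficient of T1 node i predicting
    T2 node j; rows are sources, columns targets; the diagonal holds the
    autoregressive paths. Covariate coefficients are adjustment terms, kept
    separately — covariates are not nodes.
    """

    nodes: list  # 16 NodeId, child block then parent block
    B_hat: np.ndarray  # (16, 16)
    lambda_per_node: np.ndarray  # (16,) chosen penalty per outcome node
    covariate_coefs: pd.DataFrame  # (k_cov, 16)
    n_used: int
    config: FitConfig
    scaling: dict | None = None
    cv_curves: list | None = None

    def __post_init__(self) -> None:
        if len(self.nodes) != N_NODES:
            raise ValueError("a CLPN has exactly 16 nodes")
        comm = [n.community for n in self.nodes]
        if comm.count("child") != 8 or comm.count("parent") != 8:
            raise ValueError("community must assign 8 nodes to each side")
        self.B_hat = np.asarray(self.B_hat, dtype=float)
        if self.B_hat.shape != (N_NODES, N_NODES) or not np.isfinite(self.B_hat).all():
            raise ValueError("B_hat must be a finite 16x16 matrix")

    @property
    def community(self) -> dict:
        return {n: n.community for n in self.nodes}

    @property
    def node_names(self) -> list:
        return [str(n) for n in self.nodes]

    def community_mask(self) -> np.ndarray:
        """Boolean (16,16) matrix: True where an edge crosses communities."""
        side = np.array([n.community == "child" for n in self.nodes])
        return side[:, None] != side[None, :]

    def edge_list(self) -> pd.DataFrame:
        bridge = self.community_mask()
        rows = []
        for i, src in enumerate(self.nodes):
            for j, dst in enumerate(self.nodes):
                rows.append(
                    {
                        "source": str(src),
                        "target": str(dst),
                        "weight": self.B_hat[i, j],
                        "is_autoregressive": i == j,
                        "is_bridge": bool(bridge[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def adjacency_frame(self) -> pd.DataFrame:
        """B_hat as a labeled frame (rows = T1 sources, cols = T2 targets)."""
        return pd.DataFrame(self.B_hat, index=self.node_names,
                            columns=self.node_names)

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>_edges.csv`` (long form) + ``<prefix>_meta.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.edge_list().to_csv(
            prefix.with_name(prefix.name + "_edges.csv"), index=False,
            float_format="%.10g",
        )
        meta = {
            "nodes": self.node_names,
            "lambda_per_node": self.lambda_per_node.tolist(),
            "covariate_coefs": {
                c: self.covariate_coefs[c].tolist() for c in self.covariate_coefs
            },
            "covariate_names": list(self.covariate_coefs.index),
            "n_used": self.n_used,
            "config": self.config.to_dict(),
            "orientation": "B_hat[row=source@T1, col=target@T2]",
        }
        prefix.with_name(prefix.name + "_meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "CLPNetwork":
        prefix = Path(prefix)
        edges = pd.read_csv(prefix.with_name(prefix.name + "_edges.csv"))
        meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
        nodes = [NodeId.parse(s) for s in meta["nodes"]]
        name_ix = {s: i for i, s in enumerate(meta["nodes"])}
        B = np.zeros((N_NODES, N_NODES))
        for _, r in edges.iterrows():
            B[name_ix[r["source"]], name_ix[r["target"]]] = r["weight"]
        cov = pd.DataFrame(
            meta["covariate_coefs"], index=meta.get("covariate_names", [])
        )
        return cls(
            nodes=nodes,
            B_hat=B,
            lambda_per_node=np.asarray(meta["lambda_per_node"], float),
            covariate_coefs=cov,
            n_used=int(meta["n_used"]),
            config=FitConfig(**meta["config"]),
        )


def fit_node(
    outcome: int | NodeId,
    design: DesignMatrices,
    config: FitConfig,
    nodes: list | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Cross-validated fit of a single T2 outcome node.

    Returns ``(coefficients, lambda_chosen, cv_curve)``; the coefficient
    vector is ordered as the 16 T1 symptoms followed by covariate columns.
    """
    if isinstance(outcome, NodeId):
        if nodes is None:
            raise ValueError("need the node list to resolve a NodeId outcome")
        j = [str(n) for n in nodes].index(str(outcome))
    else:
        j = int(outcome)
    X = np.hstack([design.Y1, design.X_cov])
    pf = np.concatenate(
        [
            np.ones(N_NODES),
            (np.ones if config.penalize_covariates else np.zeros)(
                design.X_cov.shape[1]
            ),
        ]
    )
    coefs, lambdas, curves = cv_lasso_multi(
        X, design.Y2, pf, config, outcomes=np.array([j])
    )
    return coefs[:, j], float(lambdas[j]), curves[j]


def fit_clpn_arrays(
    Y1: np.ndarray,
    Y2: np.ndarray,
    X_cov: np.ndarray | None,
    config: FitConfig,
    nodes: list,
    cov_names: list | None = None,
    outcomes: np.ndarray | None = None,
    keep_cv_curves: bool = False,
    scaling: dict | None = None,
) -> CLPNetwork:
    """Fit a CLPN from pre-built (already standardized) design matrices."""
    if X_cov is None:
        X_cov = np.empty((Y1.shape[0], 0))
    X = np.hstack([Y1, X_cov])
    pf = np.concatenate(
        [
            np.ones(N_NODES),
            (np.ones if config.penalize_covariates else np.zeros)(X_cov.shape[1]),
        ]
    )
    coefs, lambdas, curves = cv_lasso_multi(X, Y2, pf, config, outcomes=outcomes)
    cov_names = cov_names or [f"cov{i}" for i in range(X_cov.shape[1])]
    return CLPNetwork(
        nodes=list(nodes),
        B_hat=np.nan_to_num(coefs[:N_NODES, :], nan=0.0)
        if outcomes is not None
        else coefs[:N_NODES, :],
        lambda_per_node=lambdas,
        covariate_coefs=pd.DataFrame(
            coefs[N_NODES:, :], index=cov_names, columns=[str(n) for n in nodes]
        ),
        n_used=Y1.shape[0],
        config=config,
        scaling=scaling,
        cv_curves=curves if keep_cv_curves else None,
    )


def fit_clpn(
    panel: DyadPanel,
    config: FitConfig | None = None,
    include_covariates: bool = True,
    outcomes: np.ndarray | None = None,
    keep_cv_curves: bool = False,
) -> CLPNetwork:
    """Estimate the 16-node cross-lagged network of one dyad type.

    The panel must be reverse-scored, free of missing symptoms (exclusions
    applied) and, when covariates are included, free of missing covariates
    (imputed). ``outcomes`` restricts fitting to a subset of T2 outcome
    nodes — exact for those nodes, since the nodewise regressions are
    independent — leaving the remaining columns of ``B_hat`` at zero.
    """
    config = config or FitConfig()
    if not panel.scored:
        raise ScoringStateError("apply reverse scoring before fitting")
    gender, role = panel.dyad_type()
    design = standardize_panel(
        panel, include_covariates=include_covariates, scale=config.standardize
    )
    return fit_clpn_arrays(
        design.Y1,
        design.Y2,
        design.X_cov,
        config,
        nodes=node_ids(gender, role),
        cov_names=design.cov_labels,
        outcomes=outcomes,
        keep_cv_curves=keep_cv_curves,
        scaling=design.scaling,
    )
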