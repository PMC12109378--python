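"""Estimation uncertainty: bootstrap edge CIs, difference tests, and
case-dropping correlation-stability (CS) coefficients.

All procedures resample at the dyad level (the exchangeable unit) and re-run
the FULL estimation pipeline — standardization and cross-validated penalty
selection included — inside every replicate, so the intervals reflect
selection uncertainty and not just coefficient noise. Everything is
deterministic given its seed.

The CS coefficient of a centrality index is the largest drop proportion p in
the grid at which at least ``prob`` (default 95%) of size-⌈(1−p)n⌉
subsamples still yield an index correlating ≥ ``corr_threshold`` (default
0.70) with the full-sample index; below 0.25 the index is conventionally
called unstable, 0.25-0.50 acceptable, and ≥ 0.50 robust.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .centrality import compute_centrality
from .estimation import CLPNetwork, FitConfig, N_NODES, ZeroVarianceError, fit_clpn
from .panel import DyadPanel

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))

#: CS verdict cutpoints
CS_ACCEPTABLE = 0.25
CS_ROBUST = 0.50

FitterType = Callable[[np.ndarray, int], CLPNetwork]


def _panel_fitter(
    panel: DyadPanel, config: FitConfig, include_covariates: bool, outcomes
) -> tuple[FitterType, int]:
    def fit(rows: np.ndarray, fold_seed: int) -> CLPNetwork:
        df = panel.df.iloc[rows].reset_index(drop=True)
        # resampling repeats dyads; relabel so the resample is a valid panel
        df["dyad_id"] = [f"r{i:06d}" for i in range(len(df))]
        sub = DyadPanel(df, dict(panel.metadata))
        cfg = FitConfig(**{**config.to_dict(), "fold_seed": int(fold_seed)})
        return fit_clpn(
            sub, cfg, include_covariates=include_covariates, outcomes=outcomes
        )

    return fit, len(panel)


# ---------------------------------------------------------------------------
# Nonparametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class EdgeBootstrap:
    """Replicate-level lagged coefficient estimates and percentile CIs.

    CI endpoints are order statistics of the replicate set (lower endpoint:
    largest replicate ≤ the 2.5th percentile rank; upper: smallest ≥ the
    97.5th), so with one replicate the interval degenerates to a point.
    """

    nodes: list
    point: np.ndarray  # (16,16) full-sample estimate
    replicates: np.ndarray  # (n_kept, 16, 16)
    n_boot: int
    n_skipped: int
    seed: int
    level: float = 0.95
    outcomes: np.ndarray | None = None

    @property
    def boot_mean(self) -> np.ndarray:
        return self.replicates.mean(axis=0)

    @property
    def ci_lower(self) -> np.ndarray:
        a = (1.0 - self.level) / 2
        return np.quantile(self.replicates, a, axis=0, method="lower")

    @property
    def ci_upper(self) -> np.ndarray:
        a = (1.0 - self.level) / 2
        return np.quantile(self.replicates, 1.0 - a, axis=0, method="higher")

    def edge_table(self) -> pd.DataFrame:
        names = [str(n) for n in self.nodes]
        lo, hi, mean = self.ci_lower, self.ci_upper, self.boot_mean
        rows = []
        cols = (
            range(N_NODES)
            if self.outcomes is None
            else [int(j) for j in self.outcomes]
        )
        for i in range(N_NODES):
            for j in cols:
                rows.append(
                    {
                        "source": names[i],
                        "target": names[j],
                        "estimate": self.point[i, j],
                        "boot_mean": mean[i, j],
                        "ci_lower": lo[i, j],
                        "ci_upper": hi[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.edge_table().to_csv(
            prefix.with_name(prefix.name + "_edge_ci.csv"),
            index=False,
            float_format="%.10g",
        )
        meta = {
            "n_boot": self.n_boot,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
            "level": self.level,
        }
        prefix.with_name(prefix.name + "_boot_meta.json").write_text(
            json.dumps(meta, indent=2)
        )


def bootstrap_from_fitter(
    fit: FitterType,
    n: int,
    n_boot: int,
    seed: int,
    max_skip_frac: float = 0.10,
) -> tuple[np.ndarray, int]:
    """Resample rows with replacement and refit; returns (replicates, n_skipped).

    Replicates whose resample has a zero-variance column are skipped and
    logged; more than ``max_skip_frac`` skips is an error.
    """
    rng = np.random.default_rng(seed)
    reps, skipped = [], 0
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        try:
            net = fit(rows, fold_seed)
        except ZeroVarianceError as e:
            skipped += 1
            warnings.warn(f"bootstrap replicate skipped: {e}", stacklevel=2)
            continue
        reps.append(net.B_hat)
    if skipped > max_skip_frac * n_boot:
        raise RuntimeError(
            f"{skipped}/{n_boot} bootstrap replicates skipped (zero-variance "
            "resamples); the sample is too small or too sparse to bootstrap"
        )
    return np.asarray(reps), skipped


def bootstrap_edges(
    panel: DyadPanel,
    config: FitConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    outcomes: np.ndarray | None = None,
    include_covariates: bool = True,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of the lagged coefficient matrix.

    ``outcomes`` restricts each refit to a subset of T2 outcome nodes; the
    nodewise regressions are independent, so restricted runs are exact for
    the retained columns.
    """
    config = config or FitConfig()
    full = fit_clpn(panel, config, include_covariates, outcomes=outcomes)
    fit, n = _panel_fitter(panel, config, include_covariates, outcomes)
    reps, skipped = bootstrap_from_fitter(fit, n, n_boot, seed)
    return EdgeBootstrap(
        nodes=full.nodes,
        point=full.B_hat,
        replicates=reps,
        n_boot=n_boot,
        n_skipped=skipped,
        seed=seed,
        outcomes=outcomes,
    )


# ---------------------------------------------------------------------------
# Difference tests
# ---------------------------------------------------------------------------

@dataclass
class DifferenceTests:
    """Pairwise bootstrap difference tests.

    ``edges`` is a square boolean frame over edge labels; True where the
    bootstrap CI of the pairwise difference excludes zero. ``centrality``
    maps each index to a 16x16 boolean frame over nodes. Diagonals are False
    by definition; both matrices are symmetric.
    """

    edges: pd.DataFrame
    centrality: dict

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.edges.astype(int).to_csv(
            prefix.with_name(prefix.name + "_edge_diff.csv")
        )
        for idx, frame in self.centrality.items():
            frame.astype(int).to_csv(
                prefix.with_name(prefix.name + f"_{idx}_diff.csv")
            )


def _pairwise_excludes_zero(R: np.ndarray, level: float) -> np.ndarray:
    """(m, m) boolean: percentile CI of column differences excludes 0."""
    a = (1.0 - level) / 2
    m = R.shape[1]
    out = np.zeros((m, m), dtype=bool)
    for e in range(m):
        d = R - R[:, [e]]
        lo = np.quantile(d, a, axis=0, method="lower")
        hi = np.quantile(d, 1.0 - a, axis=0, method="higher")
        out[e] = (lo > 0) | (hi < 0)
        out[e, e] = False
    return out


def difference_tests(boot: EdgeBootstrap, level: float = 0.95) -> DifferenceTests:
    """Edge-pair and centrality-pair bootstrap difference tests."""
    names = [str(n) for n in boot.nodes]
    cols = (
        list(range(N_NODES)) if boot.outcomes is None else [int(j) for j in boot.outcomes]
    )
    edge_labels = [f"{names[i]}→{names[j]}" for i in range(N_NODES) for j in cols]
    R = boot.replicates[:, :, cols].reshape(len(boot.replicates), -1)
    edges = pd.DataFrame(
        _pairwise_excludes_zero(R, level), index=edge_labels, columns=edge_labels
    )

    # per-replicate centralities (self-loops excluded, signed sums)
    Brep = boot.replicates
    off = Brep - np.einsum("rii->ri", Brep)[:, :, None] * np.eye(N_NODES)
    side = np.array([n.community == "child" for n in boot.nodes])
    bridge = side[:, None] != side[None, :]
    cent = {
        "oei": off.sum(axis=2),
        "iei": off.sum(axis=1),
        "bei": (Brep * bridge).sum(axis=2),
    }
    centrality = {
        idx: pd.DataFrame(
            _pairwise_excludes_zero(v, level), index=names, columns=names
        )
        for idx, v in cent.items()
    }
    return DifferenceTests(edges=edges, centrality=centrality)


# ---------------------------------------------------------------------------
# Correlation-stability (case-dropping) coefficient
# ---------------------------------------------------------------------------

@dataclass
class CSResult:
    """Case-dropping stability of one centrality index."""

    index: str
    drop_grid: tuple
    correlations: dict  # p -> np.ndarray of per-subsample correlations (NaN = failed)
    corr_threshold: float
    prob: float
    cs: float
    verdict: str
    infeasible: tuple = ()

    def success_fraction(self, p: float, corr_threshold: float | None = None) -> float:
        thr = self.corr_threshold if corr_threshold is None else corr_threshold
        c = self.correlations[p]
        if len(c) == 0:
            return 0.0
        return float(np.mean(np.nan_to_num(c, nan=-np.inf) >= thr))

    def cs_at(self, corr_threshold: float) -> float:
        """CS recomputed at another correlation threshold from the stored
        subsample correlations (monotone nonincreasing in the threshold)."""
        ok = [
            p
            for p in self.drop_grid
            if p not in self.infeasible
            and self.success_fraction(p, corr_threshold) >= self.prob
        ]
        return max(ok) if ok else 0.0

    def quantile_table(self) -> pd.DataFrame:
        rows = []
        for p in self.drop_grid:
            c = self.correlations.get(p, np.array([]))
            c = c[~np.isnan(c)] if len(c) else c
            rows.append(
                {
                    "drop": p,
                    "q025": np.quantile(c, 0.025) if len(c) else np.nan,
                    "median": np.quantile(c, 0.5) if len(c) else np.nan,
                    "q975": np.quantile(c, 0.975) if len(c) else np.nan,
                    "success_frac": self.success_fraction(p),
                    "infeasible": p in self.infeasible,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "cs": self.cs,
            "verdict": self.verdict,
            "corr_threshold": self.corr_threshold,
            "prob": self.prob,
            "drop_grid": list(self.drop_grid),
            "success_frac": {
                str(p): self.success_fraction(p) for p in self.drop_grid
            },
        }


def cs_verdict(cs: float) -> str:
    if cs >= CS_ROBUST:
        return "robust"
    if cs >= CS_ACCEPTABLE:
        return "acceptable"
    return "unstable"


def cs_from_fitter(
    fit: FitterType,
    n: int,
    index: str,
    full_index: np.ndarray,
    drop_grid: tuple = DEFAULT_DROP_GRID,
    reps_per_drop: int = 50,
    corr_threshold: float = 0.70,
    prob: float = 0.95,
    seed: int = 0,
    min_rows: int = 2,
) -> CSResult:
    rng = np.random.default_rng(seed)
    full = np.asarray(full_index, dtype=float)
    correlations: dict = {}
    infeasible = []
    for p in drop_grid:
        size = int(np.ceil((1.0 - p) * n))
        if size < min_rows:
            infeasible.append(p)
            correlations[p] = np.array([])
            continue
        cors = np.full(reps_per_drop, np.nan)
        for r in range(reps_per_drop):
            rows = rng.choice(n, size=size, replace=False)
            fold_seed = int(rng.integers(0, 2**31 - 1))
            try:
                net = fit(rows, fold_seed)
            except (ZeroVarianceError, ValueError):
                continue  # failed replicate stays NaN (counts against success)
            sub = compute_centrality(net).table[index].to_numpy(float)
            if np.std(sub) == 0 or np.std(full) == 0:
                continue
            cors[r] = np.corrcoef(full, sub)[0, 1]
        correlations[p] = cors
    ok = [
        p
        for p in drop_grid
        if p not in infeasible
        and len(correlations[p])
        and np.mean(np.nan_to_num(correlations[p], nan=-np.inf) >= corr_threshold)
        >= prob
    ]
    cs = max(ok) if ok else 0.0
    return CSResult(
        index=index,
        drop_grid=tuple(drop_grid),
        correlations=correlations,
        corr_threshold=corr_threshold,
        prob=prob,
        cs=cs,
        verdict=cs_verdict(cs),
        infeasible=tuple(infeasible),
    )


def cs_coefficient(
    panel: DyadPanel,
    config: FitConfig | None = None,
    index: str = "oei",
    drop_grid: tuple = DEFAULT_DROP_GRID,
    reps_per_drop: int = 50,
    corr_threshold: float = 0.70,
    prob: float = 0.95,
    seed: int = 0,
    include_covariates: bool = True,
) -> CSResult:
    """Case-dropping CS coefficient of one centrality index.

    Subsamples WITHOUT replacement at each drop proportion, re-estimates the
    full pipeline, and correlates the raw index (all 16 nodes) with the
    full-sample index. Drop proportions whose subsample is smaller than the
    number of CV folds are marked infeasible.
    """
    config = config or FitConfig()
    full_net = fit_clpn(panel, config, include_covariates)
    full_index = compute_centrality(full_net).table[index].to_numpy(float)
    fit, n = _panel_fitter(panel, config, include_covariates, None)
    return cs_from_fitter(
        fit,
        n,
        index,
        full_index,
        drop_grid=drop_grid,
        reps_per_drop=reps_per_drop,
        corr_threshold=corr_threshold,
        prob=prob,
        seed=seed,
        min_rows=config.n_folds,
    )
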