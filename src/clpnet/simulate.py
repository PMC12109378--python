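"""Synthetic two-wave dyadic panel generator with known cross-lagged structure.

The generative model mirrors the analysis model rather than any richer data
mechanism: each of the 16 symptom variables (8 child + 8 parent) has a latent
continuous severity, with

    y_T1 ~ MVN(0, Sigma)                      (exchangeable correlations)
    y_T2 = B' y_T1 + Gamma' x + eps

The residuals ``eps`` have per-node SD ``sigma_eps`` and, by default, the
same exchangeable correlation pattern as the T1 latents: without this the
wave-2 items would be almost uncorrelated cross-sectionally (internal
consistency near zero), which no real symptom scale shows. Correlated
residuals leave the lagged regression estimands untouched — each nodewise
regression of a T2 node on the T1 block still has ``B_true[:, j]`` as its
population coefficients.

where ``B_true[i, j]`` is the lagged effect of node i at wave 1 on node j at
wave 2 (diagonal = autoregressive paths) and ``x`` are standardized
covariates. Each latent value is discretized to the 1..4 ordinal response
scale through three strictly increasing per-node cutpoints, applied on the
unit-SD scale of that node/wave, so discretization is monotone. The two
positively-worded items (D4, D6) are emitted RAW, i.e. reflected back to
``5 - score``, so the downstream reverse-scoring step sees realistic input.

Covariate cells are deleted completely at random at ``miss_rate_cov``;
symptom responses are always complete (the study design drops incomplete
dyads, so missing symptoms would only exercise the exclusion step, which has
its own fixtures).

All randomness flows through one ``numpy.random.default_rng(seed)`` (PCG64),
which is reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .items import ITEM_CODES, REVERSE_ITEMS
from .panel import COVARIATES, DYAD_TYPES, DyadPanel, WAVES

N_NODES = 16
#: generic node labels in canonical order: child D1..D8 then parent D1..D8
GENERIC_NODES = [f"C_{it}" for it in ITEM_CODES] + [f"P_{it}" for it in ITEM_CODES]

#: standardized covariate order used by Gamma_true rows
COVARIATE_EFFECTS = ("child_age", "ethnicity_nonhan", "log_income", "parent_education")

DEFAULT_COVARIATE_MODEL = {
    "age_mean": 13.8,
    "age_sd": 2.5,
    "age_range": (9.0, 16.0),
    "p_nonhan": 0.13,
    "log_income_mean": 11.15,
    "log_income_sd": 0.85,
    "education_probs": (0.45, 0.31, 0.16, 0.08),
}


class SyntheticSpecError(ValueError):
    pass


def _exchangeable(within: float, cross: float) -> np.ndarray:
    s = np.full((N_NODES, N_NODES), cross)
    s[:8, :8] = within
    s[8:, 8:] = within
    np.fill_diagonal(s, 1.0)
    return s


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study population."""

    counts: dict  # (child_gender, parent_role) -> n dyads
    B_true: np.ndarray  # (16, 16), rows = T1 source, cols = T2 target
    Gamma_true: np.ndarray  # (4, 16) effects of standardized covariates
    sigma_eps: np.ndarray  # (16,) residual SD per node
    thresholds: np.ndarray  # (16, 3) cutpoints on the unit-SD latent scale
    within_person_corr: float = 0.3
    cross_person_corr: float = 0.1
    resid_within_corr: float = 0.3
    resid_cross_corr: float = 0.1
    covariate_model: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    miss_rate_cov: float = 0.05
    seed: int = 0
    emit_latent: bool = False

    def __post_init__(self) -> None:
        self.B_true = np.asarray(self.B_true, dtype=float)
        self.Gamma_true = np.asarray(self.Gamma_true, dtype=float)
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.B_true.shape != (N_NODES, N_NODES):
            raise SyntheticSpecError("B_true must be 16x16")
        if self.Gamma_true.shape != (len(COVARIATE_EFFECTS), N_NODES):
            raise SyntheticSpecError("Gamma_true must be 4x16")
        if self.sigma_eps.shape != (N_NODES,) or (self.sigma_eps <= 0).any():
            raise SyntheticSpecError("sigma_eps must be 16 positive values")
        if self.thresholds.shape != (N_NODES, 3):
            raise SyntheticSpecError("thresholds must be 16x3")
        if not (np.diff(self.thresholds, axis=1) > 0).all():
            raise SyntheticSpecError("thresholds must be strictly increasing per node")
        if not (0.0 <= self.miss_rate_cov < 1.0):
            raise SyntheticSpecError("miss_rate_cov must lie in [0, 1)")
        for key in self.counts:
            if tuple(key) not in DYAD_TYPES:
                raise SyntheticSpecError(f"unknown dyad type {key!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    def n_dyads(self, child_gender: str | None = None) -> int:
        return int(
            sum(
                n
                for (g, _r), n in self.counts.items()
                if child_gender is None or g == child_gender
            )
        )

    def latent_t1_cov(self) -> np.ndarray:
        """Exchangeable T1 covariance: within-person vs parent-child blocks."""
        return _exchangeable(self.within_person_corr, self.cross_person_corr)

    def resid_corr(self) -> np.ndarray:
        return _exchangeable(self.resid_within_corr, self.resid_cross_corr)

    def latent_t2_sd(self) -> np.ndarray:
        """Analytic SD of the T2 latent values implied by the spec."""
        sig = self.latent_t1_cov()
        var = (
            np.einsum("ij,ik,kj->j", self.B_true, sig, self.B_true)
            + (self.Gamma_true**2).sum(axis=0)
            + self.sigma_eps**2
        )
        return np.sqrt(var)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "counts": {f"{g}-{r}": int(n) for (g, r), n in self.counts.items()},
            "B_true": self.B_true.tolist(),
            "Gamma_true": self.Gamma_true.tolist(),
            "sigma_eps": self.sigma_eps.tolist(),
            "thresholds": self.thresholds.tolist(),
            "within_person_corr": self.within_person_corr,
            "cross_person_corr": self.cross_person_corr,
            "resid_within_corr": self.resid_within_corr,
            "resid_cross_corr": self.resid_cross_corr,
            "covariate_model": {
                k: list(v) if isinstance(v, (tuple, list)) else v
                for k, v in self.covariate_model.items()
            },
            "miss_rate_cov": self.miss_rate_cov,
            "seed": self.seed,
            "emit_latent": self.emit_latent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["counts"] = {tuple(k.split("-")): int(n) for k, n in d["counts"].items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GenerationReport:
    """Realized marginals (scored scale) and covariate missingness fractions."""

    mean: dict  # wave -> (16,) realized ordinal means, scored scale
    sd: dict
    covariate_missing_frac: dict  # covariate -> fraction missing
    n_dyads: int

    def to_dict(self) -> dict:
        return {
            "n_dyads": self.n_dyads,
            "mean": {w: np.asarray(v).round(6).tolist() for w, v in self.mean.items()},
            "sd": {w: np.asarray(v).round(6).tolist() for w, v in self.sd.items()},
            "covariate_missing_frac": {
                k: round(float(v), 6) for k, v in self.covariate_missing_frac.items()
            },
            "nodes": GENERIC_NODES,
        }


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def thresholds_for_mean(target_mean: float, spacing: float = 1.0) -> np.ndarray:
    """Cutpoints ``(c, c+spacing, c+2*spacing)`` whose ordinal mean under a
    standard-normal latent equals ``target_mean``.

    The ordinal mean ``1 + sum_k P(Z > c + k*spacing)`` is strictly decreasing
    in c, so the offset is found by bisection.
    """

    def mean_of(c: float) -> float:
        ks = c + spacing * np.arange(3)
        return 1.0 + norm.sf(ks).sum()

    lo, hi = -4.0, 6.0
    if not (mean_of(hi) < target_mean < mean_of(lo)):
        raise SyntheticSpecError(f"target mean {target_mean} out of reachable range")
    c = brentq(lambda c: mean_of(c) - target_mean, lo, hi, xtol=1e-10)
    return c + spacing * np.arange(3)


# Scored-scale target marginals for the default population, child then parent,
# in the 1.1-2.1 band typical of general-population CES-D-8 item means.
DEFAULT_TARGET_MEANS = np.array(
    [1.65, 1.55, 1.48, 1.82, 1.40, 1.69, 1.51, 1.13,  # child D1..D8
     1.74, 1.70, 1.74, 2.06, 1.48, 1.97, 1.55, 1.22]  # parent D1..D8
)


def _node_index(who: str, item: str) -> int:
    return GENERIC_NODES.index(f"{who}_{item}")


# Sparse default lagged structure: autoregressive 0.3 on every node; 12
# parent<->child cross-lagged effects of 0.05-0.15, echoing the magnitude and
# the kind of pathways (parental sadness -> child sleep/unhappiness, child
# loneliness/hopelessness -> parental mood) seen in family symptom networks.
DEFAULT_CROSS_EFFECTS = (
    ("P_D7", "C_D4", 0.12),
    ("P_D7", "C_D3", 0.10),
    ("C_D5", "P_D6", 0.15),
    ("C_D8", "P_D7", 0.12),
    ("P_D5", "C_D3", 0.08),
    ("C_D3", "P_D4", 0.08),
    ("P_D4", "C_D1", 0.10),
    ("C_D1", "P_D1", 0.10),
    ("P_D2", "C_D4", 0.06),
    ("C_D4", "P_D8", 0.09),
    ("P_D8", "C_D6", 0.06),
    ("C_D6", "P_D1", 0.05),
)


def build_spec(
    counts: dict,
    B_true: np.ndarray,
    Gamma_true: np.ndarray | None = None,
    target_means: np.ndarray | None = None,
    within_person_corr: float = 0.3,
    cross_person_corr: float = 0.1,
    resid_within_corr: float = 0.3,
    resid_cross_corr: float = 0.1,
    miss_rate_cov: float = 0.05,
    seed: int = 0,
    emit_latent: bool = False,
    covariate_model: dict | None = None,
) -> SyntheticSpec:
    """Assemble a spec, choosing ``sigma_eps`` so each T2 latent has unit
    variance (standardized true coefficients then equal ``B_true``) and
    calibrating thresholds to the requested scored-scale ordinal means."""
    B_true = np.asarray(B_true, dtype=float)
    if Gamma_true is None:
        Gamma_true = np.zeros((len(COVARIATE_EFFECTS), N_NODES))
    Gamma_true = np.asarray(Gamma_true, dtype=float)
    if target_means is None:
        target_means = DEFAULT_TARGET_MEANS
    target_means = np.asarray(target_means, dtype=float)

    sig = np.full((N_NODES, N_NODES), cross_person_corr)
    sig[:8, :8] = within_person_corr
    sig[8:, 8:] = within_person_corr
    np.fill_diagonal(sig, 1.0)
    explained = np.einsum("ij,ik,kj->j", B_true, sig, B_true) + (Gamma_true**2).sum(
        axis=0
    )
    if (explained >= 0.9).any():
        raise SyntheticSpecError("lagged + covariate effects explain >=90% variance")
    sigma_eps = np.sqrt(1.0 - explained)

    thresholds = np.vstack([thresholds_for_mean(m) for m in target_means])
    return SyntheticSpec(
        counts=dict(counts),
        B_true=B_true,
        Gamma_true=Gamma_true,
        sigma_eps=sigma_eps,
        thresholds=thresholds,
        within_person_corr=within_person_corr,
        cross_person_corr=cross_person_corr,
        resid_within_corr=resid_within_corr,
        resid_cross_corr=resid_cross_corr,
        covariate_model=dict(covariate_model or DEFAULT_COVARIATE_MODEL),
        miss_rate_cov=miss_rate_cov,
        seed=seed,
        emit_latent=emit_latent,
    )


def default_study_spec(seed: int = 0, emit_latent: bool = False) -> SyntheticSpec:
    """The default population: 760 boy dyads + 709 girl dyads split roughly
    evenly between fathers and mothers, sparse cross-lagged structure, and
    ordinal marginals in the 1.1-2.1 band."""
    B = np.zeros((N_NODES, N_NODES))
    np.fill_diagonal(B, 0.3)
    for src, dst, w in DEFAULT_CROSS_EFFECTS:
        B[GENERIC_NODES.index(src), GENERIC_NODES.index(dst)] = w
    Gamma = np.zeros((len(COVARIATE_EFFECTS), N_NODES))
    Gamma[0, _node_index("C", "D3")] = 0.08  # older adolescents: worse sleep
    Gamma[0, _node_index("C", "D1")] = 0.05
    Gamma[2, _node_index("C", "D1")] = -0.05  # income protective
    Gamma[2, _node_index("P", "D1")] = -0.08
    Gamma[3, _node_index("P", "D6")] = -0.05
    counts = {
        ("boy", "father"): 380,
        ("boy", "mother"): 380,
        ("girl", "father"): 355,
        ("girl", "mother"): 354,
    }
    return build_spec(counts, B, Gamma, seed=seed, emit_latent=emit_latent)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_dyads(
    spec: SyntheticSpec,
) -> tuple[DyadPanel, GenerationReport, dict | None]:
    """Draw one panel from the spec.

    Returns ``(panel, report, latent)`` where ``latent`` is None unless
    ``spec.emit_latent``; latent tables are DataFrames of the continuous
    severities (node columns ``C_D1``..``P_D8``) per wave, on the severity
    scale (D4/D6 not reflected).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    if n == 0:
        raise SyntheticSpecError("spec contains no dyads")

    genders, roles = [], []
    for (g, r) in DYAD_TYPES:
        k = int(spec.counts.get((g, r), 0))
        genders += [g] * k
        roles += [r] * k

    # covariates -> standardized design used by Gamma
    cm = spec.covariate_model
    lo, hi = cm["age_range"]
    age = np.clip(rng.normal(cm["age_mean"], cm["age_sd"], n), lo, hi)
    nonhan = (rng.random(n) < cm["p_nonhan"]).astype(float)
    log_inc = rng.normal(cm["log_income_mean"], cm["log_income_sd"], n)
    income = np.exp(log_inc)
    edu = rng.choice(
        np.arange(1, 5), size=n, p=np.asarray(cm["education_probs"], dtype=float)
    ).astype(float)
    X = np.column_stack([age, nonhan, log_inc, edu])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd

    # latent severities
    L = np.linalg.cholesky(spec.latent_t1_cov())
    y1 = rng.standard_normal((n, N_NODES)) @ L.T
    L_eps = np.linalg.cholesky(spec.resid_corr())
    eps = (rng.standard_normal((n, N_NODES)) @ L_eps.T) * spec.sigma_eps
    y2 = y1 @ spec.B_true + Xz @ spec.Gamma_true + eps

    sd2 = spec.latent_t2_sd()
    ord1 = discretize(y1, spec.thresholds, np.ones(N_NODES))
    ord2 = discretize(y2, spec.thresholds, sd2)

    report = GenerationReport(
        mean={"T1": ord1.mean(axis=0), "T2": ord2.mean(axis=0)},
        sd={"T1": ord1.std(axis=0, ddof=1), "T2": ord2.std(axis=0, ddof=1)},
        covariate_missing_frac={},
        n_dyads=n,
    )

    # reflect positively-worded items back to raw coding
    raw1, raw2 = ord1.astype(float), ord2.astype(float)
    for item in REVERSE_ITEMS:
        for who in ("C", "P"):
            j = _node_index(who, item)
            raw1[:, j] = 5.0 - raw1[:, j]
            raw2[:, j] = 5.0 - raw2[:, j]

    # MCAR holes in covariates
    cov_cols = {
        "child_age": age.round(1),
        "ethnicity": nonhan + 1.0,
        "annual_family_income": income.round(0),
        "parent_education": edu,
    }
    for name in COVARIATES:
        col = cov_cols[name].astype(float)
        holes = rng.random(n) < spec.miss_rate_cov
        col[holes] = np.nan
        cov_cols[name] = col
        report.covariate_missing_frac[name] = float(holes.mean())

    data = {
        "dyad_id": [f"d{i:06d}" for i in range(n)],
        "child_gender": genders,
        "parent_role": roles,
        "cohabiting_T1": np.ones(n, dtype=bool),
        "cohabiting_T2": np.ones(n, dtype=bool),
    }
    for jw, (wave, raw) in enumerate(zip(WAVES, (raw1, raw2))):
        for j, node in enumerate(GENERIC_NODES):
            who, item = node.split("_")
            data[f"{who}_{item}_{wave}"] = raw[:, j]
    for name in COVARIATES:
        data[name] = cov_cols[name]

    panel = DyadPanel(
        pd.DataFrame(data),
        {"provenance": f"clpnet.simulate seed={spec.seed}", "scored": False},
    )
    latent = None
    if spec.emit_latent:
        latent = {
            "T1": pd.DataFrame(y1, columns=GENERIC_NODES),
            "T2": pd.DataFrame(y2, columns=GENERIC_NODES),
        }
    return panel, report, latent


def discretize(y: np.ndarray, thresholds: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Map latent values to ordinal 1..4 through per-node cutpoints.

    ``scale`` puts each column on the unit-SD scale the cutpoints refer to.
    Monotone per node by construction.
    """
    z = y / scale
    return 1 + (z[:, :, None] > thresholds[None, :, :]).sum(axis=2)
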