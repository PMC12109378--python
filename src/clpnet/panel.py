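"""Two-wave dyadic panel data model.

One row per parent-adolescent dyad, with the 8 CES-D-8 item responses of each
member at each of two waves (32 symptom columns), cohabitation flags, and
demographic covariates. Internally symptom columns are named
``{who}_{item}_{wave}`` with generic roles ``C`` (child) and ``P`` (parent),
e.g. ``C_D4_T1``; role-coded headers (``B_D4_T1``) are accepted on read via a
column map and emitted on write for homogeneous (single dyad-type) panels.

Missing symptom responses are never imputed: dyads with any missing response
at either wave, or not cohabiting at either wave, are dropped by
:func:`apply_exclusions` (missingness checked first for log attribution).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .items import ITEM_CODES, REVERSE_ITEMS, ROLE_LETTERS

WAVES = ("T1", "T2")
WHO = ("C", "P")

#: covariate columns, in canonical order
COVARIATES = ("child_age", "ethnicity", "annual_family_income", "parent_education")
CATEGORICAL_COVARIATES = ("ethnicity", "parent_education")
COVARIATE_LEVELS = {"ethnicity": (1, 2), "parent_education": (1, 2, 3, 4)}

META_COLUMNS = (
    "dyad_id",
    "child_gender",
    "parent_role",
    "cohabiting_T1",
    "cohabiting_T2",
)

SYMPTOM_COLUMNS = tuple(
    f"{who}_{item}_{wave}" for who in WHO for wave in WAVES for item in ITEM_CODES
)

ALL_COLUMNS = META_COLUMNS + SYMPTOM_COLUMNS + COVARIATES


class PanelConfigError(ValueError):
    """A column map or CSV header does not resolve the mandatory columns."""


class PanelValidationError(ValueError):
    """A cell value violates the data model (e.g. symptom response of 5)."""


class ScoringStateError(RuntimeError):
    """Reverse scoring applied twice, or an op needs scored/raw data."""


def symptom_columns(who: str | None = None, wave: str | None = None) -> list[str]:
    """Internal symptom column names, optionally filtered by member/wave."""
    return [
        c
        for c in SYMPTOM_COLUMNS
        if (who is None or c.startswith(who + "_"))
        and (wave is None or c.endswith("_" + wave))
    ]


@dataclass(frozen=True)
class DyadRecord:
    """One parent-adolescent dyad (validated, typed view of a panel row)."""

    dyad_id: str
    child_gender: str  # 'boy' | 'girl'
    parent_role: str  # 'father' | 'mother'
    child_items_T1: tuple  # 8 responses, np.nan for missing
    child_items_T2: tuple
    parent_items_T1: tuple
    parent_items_T2: tuple
    cohabiting_T1: bool
    cohabiting_T2: bool
    child_age: float = np.nan
    ethnicity: float = np.nan  # 1 = Han, 2 = non-Han
    annual_family_income: float = np.nan
    parent_education: float = np.nan  # ordinal 1..4
    scored: bool = False

    def apply_reverse_scoring(self) -> "DyadRecord":
        """Reverse-score D4 and D6 (``scored = 5 - raw``); refuses to re-apply."""
        if self.scored:
            raise ScoringStateError("reverse scoring already applied to this record")
        rev_idx = [i for i, it in enumerate(ITEM_CODES) if it in REVERSE_ITEMS]

        def rev(items: tuple) -> tuple:
            out = list(items)
            for i in rev_idx:
                if not _isna(out[i]):
                    out[i] = 5 - out[i]
            return tuple(out)

        return replace(
            self,
            child_items_T1=rev(self.child_items_T1),
            child_items_T2=rev(self.child_items_T2),
            parent_items_T1=rev(self.parent_items_T1),
            parent_items_T2=rev(self.parent_items_T2),
            scored=True,
        )


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


@dataclass
class DyadPanel:
    """A rectangular two-wave dyadic dataset.

    ``df`` holds one row per dyad with the canonical columns; ``metadata``
    records provenance, wave labels and whether reverse scoring has been
    applied.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("waves", list(WAVES))
        self.metadata.setdefault("provenance", "unspecified")
        self.metadata.setdefault("scored", False)
        validate_panel_frame(self.df)

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def scored(self) -> bool:
        return bool(self.metadata["scored"])

    def copy(self) -> "DyadPanel":
        return DyadPanel(self.df.copy(), dict(self.metadata))

    def symptom_values(self, who: str | None = None, wave: str | None = None) -> np.ndarray:
        return self.df[symptom_columns(who, wave)].to_numpy(dtype=float)

    def is_homogeneous(self) -> bool:
        return (
            self.df["child_gender"].nunique() <= 1
            and self.df["parent_role"].nunique() <= 1
        )

    def dyad_type(self) -> tuple[str, str]:
        if not self.is_homogeneous():
            raise ValueError("panel mixes dyad types; split it first")
        return (
            str(self.df["child_gender"].iloc[0]),
            str(self.df["parent_role"].iloc[0]),
        )

    def records(self) -> Iterator[DyadRecord]:
        scored = self.scored
        for _, row in self.df.iterrows():
            yield DyadRecord(
                dyad_id=str(row["dyad_id"]),
                child_gender=row["child_gender"],
                parent_role=row["parent_role"],
                child_items_T1=tuple(row[f"C_{it}_T1"] for it in ITEM_CODES),
                child_items_T2=tuple(row[f"C_{it}_T2"] for it in ITEM_CODES),
                parent_items_T1=tuple(row[f"P_{it}_T1"] for it in ITEM_CODES),
                parent_items_T2=tuple(row[f"P_{it}_T2"] for it in ITEM_CODES),
                cohabiting_T1=bool(row["cohabiting_T1"]),
                cohabiting_T2=bool(row["cohabiting_T2"]),
                child_age=float(row["child_age"]),
                ethnicity=float(row["ethnicity"]),
                annual_family_income=float(row["annual_family_income"]),
                parent_education=float(row["parent_education"]),
                scored=scored,
            )


def validate_panel_frame(df: pd.DataFrame) -> None:
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelConfigError(f"panel is missing mandatory columns: {missing}")
    if df["dyad_id"].duplicated().any():
        dup = df.loc[df["dyad_id"].duplicated(), "dyad_id"].iloc[0]
        raise PanelValidationError(f"duplicate dyad_id {dup!r}")
    bad_gender = set(df["child_gender"].dropna()) - {"boy", "girl"}
    if bad_gender:
        raise PanelValidationError(f"unknown child_gender values: {sorted(bad_gender)}")
    bad_role = set(df["parent_role"].dropna()) - {"father", "mother"}
    if bad_role:
        raise PanelValidationError(f"unknown parent_role values: {sorted(bad_role)}")
    for col in SYMPTOM_COLUMNS:
        v = df[col].to_numpy(dtype=float)
        ok = np.isnan(v) | np.isin(v, (1.0, 2.0, 3.0, 4.0))
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise PanelValidationError(
                f"symptom column {col!r}, row {i}: value {v[i]!r} not in "
                "{1,2,3,4} or missing"
            )
    for col, levels in COVARIATE_LEVELS.items():
        v = df[col].to_numpy(dtype=float)
        ok = np.isnan(v) | np.isin(v, np.asarray(levels, dtype=float))
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise PanelValidationError(
                f"covariate {col!r}, row {i}: value {v[i]!r} not in {levels} or missing"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def default_column_map() -> dict[str, str]:
    """Identity map for the canonical ``C_/P_`` column scheme."""
    return {c: c for c in ALL_COLUMNS}


def role_coded_column_map(child_gender: str, parent_role: str) -> dict[str, str]:
    """Column map for a homogeneous CSV with role-coded headers (``B_D4_T1``)."""
    c = ROLE_LETTERS[("child", child_gender)]
    p = ROLE_LETTERS[("parent", parent_role)]
    m = default_column_map()
    for col in SYMPTOM_COLUMNS:
        who, item, wave = col.split("_")
        letter = c if who == "C" else p
        m[col] = f"{letter}_{item}_{wave}"
    return m


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a column map from JSON or YAML (canonical name -> CSV header)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise PanelConfigError(f"column map in {path} must be a mapping")
    m = default_column_map()
    m.update({str(k): str(v) for k, v in raw.items()})
    return m


def read_panel(
    path: str | Path,
    column_map: dict[str, str] | str | Path | None = None,
    provenance: str | None = None,
    scored: bool = False,
) -> DyadPanel:
    """Read a wide dyadic panel CSV into a validated :class:`DyadPanel`.

    ``column_map`` maps canonical column names to the CSV's headers (a dict,
    or a path to a JSON/YAML file). Empty cells and ``NA`` are treated as
    missing; any symptom value outside {1,2,3,4} is a validation error naming
    the row and column.
    """
    if column_map is None:
        cmap = default_column_map()
    elif isinstance(column_map, (str, Path)):
        cmap = load_column_map(column_map)
    else:
        cmap = default_column_map()
        cmap.update(column_map)

    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise PanelConfigError(
            f"CSV {path} is missing mandatory columns: {sorted(set(missing))}"
        )
    out = pd.DataFrame(index=df.index)
    for canon, src in cmap.items():
        out[canon] = df[src]
    out["dyad_id"] = out["dyad_id"].astype(str)
    for col in ("cohabiting_T1", "cohabiting_T2"):
        out[col] = _parse_bool(out[col], col)
    for col in SYMPTOM_COLUMNS + COVARIATES:
        out[col] = pd.to_numeric(out[col], errors="raise")
    meta = {"provenance": provenance or str(path), "scored": scored}
    return DyadPanel(out.reset_index(drop=True), meta)


def _parse_bool(s: pd.Series, name: str) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False, 1.0: True, 0.0: False,
        "True": True, "False": False, "true": True, "false": False,
        "1": True, "0": False,
    }
    def conv(x):
        if x in mapping:
            return mapping[x]
        raise PanelValidationError(f"column {name!r}: cannot parse boolean {x!r}")
    return s.map(conv)


def write_panel(panel: DyadPanel, path: str | Path, role_coded: bool = False) -> None:
    """Write a panel CSV in the canonical scheme.

    With ``role_coded=True`` (homogeneous panels only) the symptom headers use
    the dyad type's role letters, e.g. ``B_D4_T1``.
    """
    df = panel.df[list(ALL_COLUMNS)].copy()
    if role_coded:
        gender, role = panel.dyad_type()
        cmap = role_coded_column_map(gender, role)
        df = df.rename(columns=cmap)
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Scoring, exclusions, splitting
# ---------------------------------------------------------------------------

def apply_reverse_scoring(panel: DyadPanel) -> DyadPanel:
    """Reverse-score D4 and D6 for every member at every wave.

    The panel carries a ``scored`` flag; applying twice is a state error
    (the transform is self-inverse, so silent re-application would corrupt
    the data undetectably).
    """
    if panel.scored:
        raise ScoringStateError("panel is already reverse-scored")
    df = panel.df.copy()
    for col in SYMPTOM_COLUMNS:
        item = col.split("_")[1]
        if item in REVERSE_ITEMS:
            df[col] = 5.0 - df[col]
    meta = dict(panel.metadata)
    meta["scored"] = True
    return DyadPanel(df, meta)


@dataclass
class ExclusionLog:
    """Counts of dyads removed, attributed to the first rule each tripped."""

    input_size: int
    missing_symptoms: int
    not_cohabiting: int

    @property
    def retained(self) -> int:
        return self.input_size - self.missing_symptoms - self.not_cohabiting

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "missing_symptoms": self.missing_symptoms,
            "not_cohabiting": self.not_cohabiting,
            "retained": self.retained,
        }


def apply_exclusions(panel: DyadPanel) -> tuple[DyadPanel, ExclusionLog]:
    """Drop dyads with any missing symptom response or non-cohabitation.

    A dyad is removed if either member has a missing item response at either
    wave, or if the pair was not cohabiting at either wave. Each removed dyad
    is counted once, under missingness first.
    """
    df = panel.df
    miss = df[list(SYMPTOM_COLUMNS)].isna().any(axis=1).to_numpy()
    not_cohab = ~(df["cohabiting_T1"].astype(bool) & df["cohabiting_T2"].astype(bool))
    not_cohab = not_cohab.to_numpy()
    keep = ~miss & ~not_cohab
    log = ExclusionLog(
        input_size=len(df),
        missing_symptoms=int(miss.sum()),
        not_cohabiting=int((not_cohab & ~miss).sum()),
    )
    out = DyadPanel(df.loc[keep].reset_index(drop=True), dict(panel.metadata))
    return out, log


DYAD_TYPES = (
    ("boy", "father"),
    ("boy", "mother"),
    ("girl", "father"),
    ("girl", "mother"),
)


def split_by_dyad_type(panel: DyadPanel) -> dict[tuple[str, str], DyadPanel]:
    """Partition into the four (child_gender, parent_role) subpanels."""
    out = {}
    for gender, role in DYAD_TYPES:
        mask = (panel.df["child_gender"] == gender) & (panel.df["parent_role"] == role)
        sub = panel.df.loc[mask].reset_index(drop=True)
        if len(sub) == 0:
            warnings.warn(f"{gender}-{role} subpanel is empty", stacklevel=2)
        out[(gender, role)] = DyadPanel(sub, dict(panel.metadata))
    return out


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an (n_persons, k_items) score matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances)/variance(total score))``,
    sample variances (ddof=1). Returns NaN (with a warning) when the total
    score has zero variance.
    """
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 persons and 2 items")
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("total score has zero variance; alpha undefined", stacklevel=2)
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class DescriptiveTable:
    """Item-level means/SDs by member and wave, plus per-wave Cronbach's alpha."""

    table: pd.DataFrame  # columns: item, member, wave, mean, sd
    alpha: dict  # wave -> alpha pooled over persons

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def describe(panel: DyadPanel) -> DescriptiveTable:
    """Per item x member x wave mean/SD and pooled per-wave Cronbach's alpha.

    Alpha is computed on scored items, stacking child and parent response
    vectors within a wave (one alpha per wave, as reported for the scale as a
    whole rather than per subgroup).
    """
    rows = []
    for who, member in (("C", "child"), ("P", "parent")):
        for wave in WAVES:
            vals = panel.symptom_values(who, wave)
            for j, item in enumerate(ITEM_CODES):
                col = vals[:, j]
                col = col[~np.isnan(col)]
                rows.append(
                    {
                        "item": item,
                        "member": member,
                        "wave": wave,
                        "mean": float(col.mean()) if col.size else np.nan,
                        "sd": float(col.std(ddof=1)) if col.size > 1 else np.nan,
                        "n": int(col.size),
                    }
                )
    alpha = {}
    for wave in WAVES:
        stacked = np.vstack(
            [panel.symptom_values("C", wave), panel.symptom_values("P", wave)]
        )
        stacked = stacked[~np.isnan(stacked).any(axis=1)]
        alpha[wave] = cronbach_alpha(stacked) if len(stacked) >= 2 else float("nan")
    return DescriptiveTable(pd.DataFrame(rows), alpha)
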