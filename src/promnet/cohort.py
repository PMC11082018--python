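"""Cohort handling: validation, scaling, and subgroup stratification.

The analysis compares symptom networks between patient subgroups defined
three ways: disease status (preoperative vs. postoperative, with
progressive-disease assessments excluded from the postoperative side),
tumor grade (II vs. III/IV), and fatigue status (CIS fatigue-severity
score below vs. at-or-above the cut-off of 27; the four CIS nodes are then
excluded from those networks). Within each side a patient contributes at
most one assessment; a patient may legitimately appear on both sides
(e.g. one preoperative and one postoperative assessment) unless the
cross-subgroup deduplication sensitivity analysis removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import (
    CIS_NODES,
    DISEASE_STATUSES,
    FATIGUE_CUTOFF,
    FATIGUE_NODE,
    META_COLUMNS,
    POSTOPERATIVE_STATUSES,
    TUMOR_GRADES,
)

SCHEMES = ("disease_status", "tumor_grade", "fatigue_status")
SELECTION_RULES = ("earliest", "latest", "random")


def node_columns(table: pd.DataFrame) -> list[str]:
    """Score columns, i.e. everything that is not assessment metadata."""
    return [c for c in table.columns if c not in META_COLUMNS]


def score_matrix(table: pd.DataFrame) -> pd.DataFrame:
    return table[node_columns(table)]


@dataclass(frozen=True)
class SubgroupSpec:
    """Which stratification to run and how to pick one row per patient.

    The fatigue-status scheme forces the 17-node set (CIS nodes removed)
    because the sample is already stratified on the CIS fatigue score.
    """

    scheme: str = "disease_status"
    node_set: str = "full_21"
    selection_rule: str = "earliest"
    dedup_policy: str = "per-subgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.node_set not in ("full_21", "no_cis_17"):
            raise ValueError("node_set must be 'full_21' or 'no_cis_17'")
        if self.selection_rule not in SELECTION_RULES:
            raise ValueError(f"selection_rule must be one of {SELECTION_RULES}")
        if self.dedup_policy not in ("per-subgroup", "cross-subgroup"):
            raise ValueError("dedup_policy must be 'per-subgroup' or 'cross-subgroup'")
        if self.scheme == "fatigue_status" and self.node_set != "no_cis_17":
            object.__setattr__(self, "node_set", "no_cis_17")


def zscore_scale(table: pd.DataFrame,
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Standardize each score column to mean 0, sample SD 1 (ddof=1).

    Missing entries are preserved; the statistics are computed over the
    observed subset of each column. Spearman-based estimation is invariant
    to this monotone rescaling; it is applied for comparability of
    reported weights and z-score displays.
    """
    labels = labels if labels is not None else node_columns(table)
    out = table.copy()
    for lab in labels:
        col = out[lab].astype(float)
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(f"column '{lab}' has fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column '{lab}' has zero variance")
        out[lab] = (col - obs.mean()) / sd
    return out


def assign_fatigue_status(table: pd.DataFrame) -> pd.Series:
    """Label each assessment fatigued / non_fatigued from the raw CIS
    fatigue-severity score (cut-off: score >= 27 is fatigued).

    Assessments with a missing fatigue-severity score get NA and are
    ineligible for the fatigue-status stratification. Must be applied to
    raw (unscaled) scores.
    """
    if FATIGUE_NODE not in table.columns:
        raise ValueError(f"fatigue-severity column '{FATIGUE_NODE}' absent")
    score = table[FATIGUE_NODE].astype(float)
    out = pd.Series(pd.NA, index=table.index, dtype="object")
    out[score >= FATIGUE_CUTOFF] = "fatigued"
    out[score < FATIGUE_CUTOFF] = "non_fatigued"
    return out


def _select_one_per_patient(table: pd.DataFrame, rule: str,
                            seed: int = 0) -> pd.DataFrame:
    """Keep at most one assessment per patient (stable, deterministic)."""
    if table.empty:
        return table
    t = table.sort_values(["patient_id", "timepoint", "assessment_id"],
                          kind="mergesort")
    if rule == "earliest":
        return t.groupby("patient_id", sort=False).head(1)
    if rule == "latest":
        return t.groupby("patient_id", sort=False).tail(1)
    rng = np.random.default_rng(seed)
    picks = []
    for _, grp in t.groupby("patient_id", sort=False):
        picks.append(grp.index[rng.integers(len(grp))])
    return t.loc[picks]


def build_subgroups(table: pd.DataFrame,
                    spec: SubgroupSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split assessments into the two comparison subgroups.

    disease_status: A = preoperative, B = postoperative on active
    treatment or stable (progression excluded entirely). tumor_grade:
    A = grade II, B = grade III/IV. fatigue_status: A = non-fatigued,
    B = fatigued, on 17 nodes. Each side keeps one assessment per patient
    according to the selection rule.
    """
    if spec.scheme == "disease_status":
        A = table[table["disease_status"] == "preoperative"]
        B = table[table["disease_status"].isin(POSTOPERATIVE_STATUSES)]
    elif spec.scheme == "tumor_grade":
        A = table[table["tumor_grade"] == "II"]
        B = table[table["tumor_grade"].isin(["III", "IV"])]
    else:
        status = assign_fatigue_status(table)
        A = table[status == "non_fatigued"]
        B = table[status == "fatigued"]

    A = _select_one_per_patient(A, spec.selection_rule, spec.seed)
    B = _select_one_per_patient(B, spec.selection_rule, spec.seed + 1)

    if spec.node_set == "no_cis_17":
        A = drop_nodes(A, list(CIS_NODES))
        B = drop_nodes(B, list(CIS_NODES))

    names = {
        "disease_status": ("preoperative", "postoperative"),
        "tumor_grade": ("grade II", "grade III/IV"),
        "fatigue_status": ("non-fatigued", "fatigued"),
    }[spec.scheme]
    for side, name in zip((A, B), names):
        if side.empty:
            raise ValueError(f"subgroup '{name}' is empty")

    if spec.dedup_policy == "cross-subgroup":
        A, B = dedup_cross_subgroup(A, B, keep_side="B")
    return A.reset_index(drop=True), B.reset_index(drop=True)


def drop_nodes(table: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Remove score columns; duplicate or unknown labels are errors."""
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in drop list")
    cols = set(node_columns(table))
    unknown = [lab for lab in labels if lab not in cols]
    if unknown:
        raise ValueError(f"unknown node labels: {unknown}")
    return table.drop(columns=list(labels))


def dedup_cross_subgroup(A: pd.DataFrame, B: pd.DataFrame,
                         keep_side: str = "B") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove patients present in both sides from the side not kept.

    Sensitivity analysis ensuring each patient contributes one data point
    per comparison.
    """
    if keep_side not in ("A", "B"):
        raise ValueError("keep_side must be 'A' or 'B'")
    shared = set(A["patient_id"]) & set(B["patient_id"])
    if keep_side == "B":
        A = A[~A["patient_id"].isin(shared)]
    else:
        B = B[~B["patient_id"].isin(shared)]
    return A.reset_index(drop=True), B.reset_index(drop=True)


def validate_table(table: pd.DataFrame,
                   node_labels: list[str] | None = None) -> dict:
    """Schema and range checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []
    missing_meta = [c for c in META_COLUMNS if c not in table.columns]
    if missing_meta:
        errors.append(f"missing mandatory columns: {missing_meta}")
        return {"errors": errors, "warnings": warnings}

    nodes = node_labels if node_labels is not None else node_columns(table)
    absent = [c for c in nodes if c not in table.columns]
    if absent:
        errors.append(f"missing node columns: {absent}")
    dup = table.duplicated(subset=["patient_id", "assessment_id"])
    if dup.any():
        keys = table.loc[dup, ["patient_id", "assessment_id"]]
        errors.append("duplicated (patient_id, assessment_id) keys: "
                      + "; ".join(f"({r.patient_id}, {r.assessment_id})"
                                  for r in keys.itertuples()))
    bad_status = set(table["disease_status"].dropna()) - set(DISEASE_STATUSES)
    if bad_status:
        errors.append(f"unknown disease_status values {sorted(bad_status)}; "
                      f"allowed: {list(DISEASE_STATUSES)}")
    bad_grade = set(table["tumor_grade"].dropna().astype(str)) - set(TUMOR_GRADES)
    if bad_grade:
        errors.append(f"unknown tumor_grade values {sorted(bad_grade)}; "
                      f"allowed: {list(TUMOR_GRADES)}")
    from .instruments import SCORE_SCALES

    for lab in nodes:
        if lab not in table.columns or lab not in SCORE_SCALES:
            continue
        lo, hi, _ = SCORE_SCALES[lab]
        col = table[lab].dropna().astype(float)
        if ((col < lo) | (col > hi)).any():
            warnings.append(f"column '{lab}' has values outside [{lo}, {hi}]")
    frac_missing = score_matrix(table)[nodes].isna().mean().mean() if nodes else 0
    if frac_missing > 0.2:
        warnings.append(f"high missingness: {frac_missing:.0%} of scores")
    return {"errors": errors, "warnings": warnings}


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    report = validate_table(table)
    if report["errors"]:
        raise ValueError("invalid cohort table: " + " | ".join(report["errors"]))
    return table
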