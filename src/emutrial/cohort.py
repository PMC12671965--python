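"""Cohort construction: eligibility, strategy assignment and the
baseline covariate vector.

Baseline is the date of the first endocrine dispensation; the assigned
strategy is the drug class of that fill (any of letrozole, anastrozole
or exemestane counts as the aromatase-inhibitor class). Eligibility is
applied in a fixed order and every criterion's removals are recorded in
an exclusion ledger so the selection flowchart can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .config import (AI_DRUGS, DAYS_PER_MONTH, FOLLOWUP_MONTHS,
                     EligibilityCriteria)
from .errors import ConfigurationError, SchemaError

__all__ = [
    "AI_CLASS", "TAM_CLASS",
    "CATEGORICAL_LEVELS", "BINARY_COVARIATES", "COMORBIDITY_FLAGS", "DRUG_FLAGS",
    "assign_strategy", "apply_eligibility", "assemble_baseline_covariates",
    "covariate_design_matrix",
]

AI_CLASS = "aromatase_inhibitor"
TAM_CLASS = "tamoxifen"

#: five-year follow-up cap in whole days (60 x 30.4375)
FIVE_YEARS_DAYS = int(round(FOLLOWUP_MONTHS * DAYS_PER_MONTH))

#: declared level sets (first level = reference); "missing" is an
#: ordinary level wherever the source registry can leave a blank
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "stage": ["1", "2", "3"],
    "t_class": ["T1", "T2", "T3_T4"],
    "n_class": ["N0", "N1plus"],
    "grade": ["1", "2", "3", "missing"],
    "her2": ["negative", "positive", "missing"],
    "side": ["right", "left"],
    "marital_status": ["married_cohabiting", "single", "divorced_widowed"],
    "education": ["pre_secondary", "high_school", "post_secondary", "missing"],
    "employment": ["employed", "not_employed", "missing"],
}

COMORBIDITY_FLAGS = ("cerebrovascular_disease", "diabetes", "copd",
                     "cardiovascular_disease")
DRUG_FLAGS = ("diabetes_drugs", "anticoagulants", "antidepressants",
              "nsaids", "opioids", "hormone_replacement_therapy")
TUMOR_FLAGS = ("chemotherapy", "radiotherapy", "antibody_treatment")
BINARY_COVARIATES = TUMOR_FLAGS + COMORBIDITY_FLAGS + DRUG_FLAGS

_REQUIRED_PATIENT_COLUMNS = (
    "patient_id", "birth_date", "diagnosis_date", "surgery_date",
    "clear_margins", "hr_positive", "stage",
)


def _require_columns(frame: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing column(s) {missing}")


def _as_datetime(s: pd.Series) -> pd.Series:
    if pd.api.types.is_datetime64_any_dtype(s):
        return s
    return pd.to_datetime(s, format="ISO8601", errors="coerce")


def assign_strategy(dispensations: pd.DataFrame) -> pd.DataFrame:
    """Per patient: first endocrine fill date, assigned strategy, and an
    ambiguity flag for same-day first fills of both drug classes.

    Returns a frame indexed by patient_id with columns
    ``baseline_date``, ``strategy`` and ``ambiguous``.
    """
    _require_columns(dispensations, ("patient_id", "drug", "date"), "dispensations")
    if not len(dispensations):
        return pd.DataFrame(columns=["baseline_date", "strategy", "ambiguous"],
                            index=pd.Index([], name="patient_id"))
    d = dispensations.copy()
    d["date"] = _as_datetime(d["date"])
    d["drug_class"] = np.where(d["drug"].isin(AI_DRUGS), AI_CLASS, TAM_CLASS)
    first_date = d.groupby("patient_id")["date"].min()
    d = d.merge(first_date.rename("first_date"), on="patient_id")
    at_first = d[d["date"] == d["first_date"]]
    classes = at_first.groupby("patient_id")["drug_class"].agg(["nunique", "first"])
    out = pd.DataFrame({
        "baseline_date": first_date,
        "strategy": classes["first"],
        "ambiguous": classes["nunique"] > 1,
    })
    out.index.name = "patient_id"
    return out


def apply_eligibility(
    patients: pd.DataFrame,
    dispensations: pd.DataFrame,
    criteria: EligibilityCriteria | None = None,
    admin_end: date = date(2015, 12, 31),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the emulation's eligibility criteria in order.

    Returns ``(eligible, ledger)``: the eligible cohort (one row per
    patient with baseline date, strategy and follow-up end) and the
    exclusion ledger (criterion, n_removed, in application order, with a
    trailing "eligible" row). Re-applying to its own output removes
    nobody.
    """
    criteria = criteria or EligibilityCriteria()
    _require_columns(patients, _REQUIRED_PATIENT_COLUMNS, "patients")
    pt = patients.copy()
    for col in ("birth_date", "diagnosis_date", "surgery_date",
                "death_date", "emigration_date"):
        if col in pt.columns:
            pt[col] = _as_datetime(pt[col])
    pt = pt.set_index("patient_id", drop=False)
    # tolerate re-application to a previously built cohort table
    pt = pt.drop(columns=[c for c in ("baseline_date", "strategy", "ambiguous",
                                      "followup_end_date", "end_reason",
                                      "age_at_baseline") if c in pt.columns])

    firsts = assign_strategy(dispensations)
    pt = pt.join(firsts, how="left")

    ledger_rows: list[tuple[str, int]] = []
    alive = pd.Series(True, index=pt.index)

    def drop(mask: pd.Series, label: str) -> None:
        removed = int((alive & mask).sum())
        ledger_rows.append((label, removed))
        alive[mask] = False

    if "sex" in pt.columns:
        drop(pt["sex"].astype(str).str.upper() != "F", "not female")
    drop(pt["baseline_date"].isna(), "no endocrine dispensation")
    drop(pt["ambiguous"].notna() & (pt["ambiguous"] == True),  # noqa: E712
         "ambiguous first fill")

    start = pd.Timestamp(criteria.enrollment_start)
    end = pd.Timestamp(criteria.enrollment_end)
    drop(~pt["baseline_date"].between(start, end),
         "first dispensation outside study window")
    gap = (pt["baseline_date"] - pt["surgery_date"]).dt.days
    drop(pt["surgery_date"].isna() | (gap < 0)
         | (gap > criteria.max_surgery_to_dispensation_days),
         "first dispensation not within 9 months after surgery")
    if criteria.require_clear_margins:
        drop(pt["clear_margins"].fillna(0).astype(float) != 1,
             "surgery without clear margins")
    if criteria.require_hr_positive:
        drop(pt["hr_positive"].fillna(0).astype(float) != 1,
             "not hormone receptor positive")
    drop(~pt["stage"].astype(str).isin([str(s) for s in criteria.allowed_stages]),
         "stage outside 1-3")

    age_at_dx = (pt["diagnosis_date"] - pt["birth_date"]).dt.days / 365.25
    if criteria.menopause_flag_column and criteria.menopause_flag_column in pt.columns:
        post = (pt[criteria.menopause_flag_column].fillna(0).astype(float) == 1) \
            | (age_at_dx >= criteria.postmenopausal_min_age)
    else:
        post = age_at_dx >= criteria.postmenopausal_min_age
    drop(~post, "not postmenopausal")
    age_at_baseline = (pt["baseline_date"] - pt["birth_date"]).dt.days / 365.25
    drop(age_at_baseline < criteria.min_age, "age<40")

    for col in criteria.exclusion_flag_columns:
        if col in pt.columns:
            drop(pt[col].fillna(0).astype(float) == 1, col)

    eligible = pt[alive].copy()
    eligible["age_at_baseline"] = age_at_baseline[alive]

    # follow-up terminates at the first of death, emigration, 5 years,
    # administrative end
    admin = pd.Timestamp(admin_end)
    five_years = eligible["baseline_date"] + pd.Timedelta(days=FIVE_YEARS_DAYS)
    candidates = pd.DataFrame({
        "death": eligible.get("death_date", pd.Series(pd.NaT, index=eligible.index)),
        "emigration": eligible.get("emigration_date",
                                   pd.Series(pd.NaT, index=eligible.index)),
        "five_years": five_years,
        "admin_end": admin,
    })
    end_date = candidates.min(axis=1)
    # ties resolve in column order: death > emigration > 5y > admin end
    reason = candidates.eq(end_date, axis=0).idxmax(axis=1)
    eligible["followup_end_date"] = end_date
    eligible["end_reason"] = reason

    ledger_rows.append(("eligible", int(alive.sum())))
    ledger = pd.DataFrame(ledger_rows, columns=["criterion", "n_removed"])
    keep_cols = [c for c in eligible.columns if c not in ("ambiguous",)]
    return eligible[keep_cols].reset_index(drop=True), ledger


def assemble_baseline_covariates(
    eligible: pd.DataFrame,
    diagnoses: pd.DataFrame,
    drug_covariates: pd.DataFrame,
    criteria: EligibilityCriteria | None = None,
) -> pd.DataFrame:
    """Build the baseline covariate vector L for every eligible patient.

    Comorbidity flags use all recorded history strictly up to and
    including baseline; co-medication flags use a 6-month (configurable)
    lookback before baseline; continuous covariates are computed at
    baseline; blank categoricals map to the explicit "missing" level.
    Records dated after baseline never contribute.
    """
    criteria = criteria or EligibilityCriteria()
    _require_columns(eligible, ("patient_id", "baseline_date", "strategy"), "eligible")
    el = eligible.set_index("patient_id")
    baseline = _as_datetime(el["baseline_date"])

    cov = pd.DataFrame(index=el.index)
    cov["strategy"] = el["strategy"]
    cov["age"] = el["age_at_baseline"] if "age_at_baseline" in el else (
        (baseline - _as_datetime(el["birth_date"])).dt.days / 365.25)
    cov["baseline_year"] = baseline.dt.year.astype(str)
    cov["time_from_diagnosis_days"] = (
        baseline - _as_datetime(el["diagnosis_date"])).dt.days.astype(float)

    for name, levels in CATEGORICAL_LEVELS.items():
        if name not in el.columns:
            raise ConfigurationError(f"covariate {name!r} absent from cohort table")
        vals = el[name].astype(object)
        vals = vals.where(~(vals.isna() | (vals.astype(str).str.strip() == "")),
                          "missing").astype(str)
        allowed = set(levels) | {"missing"}
        bad = sorted(set(vals.unique()) - allowed)
        if bad:
            raise ConfigurationError(
                f"covariate {name!r} has undeclared level(s) {bad}")
        cov[name] = vals

    for name in TUMOR_FLAGS:
        if name not in el.columns:
            raise ConfigurationError(f"covariate {name!r} absent from cohort table")
        cov[name] = el[name].fillna(0).astype(int)

    # comorbidity flags: any qualifying diagnosis on/before baseline
    dg = diagnoses.copy()
    if len(dg):
        _require_columns(dg, ("patient_id", "condition", "date"), "diagnoses")
        dg["date"] = _as_datetime(dg["date"])
        dg = dg.merge(baseline.rename("baseline"), left_on="patient_id",
                      right_index=True, how="inner")
        dg = dg[dg["date"] <= dg["baseline"]]
    for name in COMORBIDITY_FLAGS:
        hit = dg[dg["condition"] == name]["patient_id"].unique() if len(dg) else []
        cov[name] = cov.index.isin(hit).astype(int)

    # co-medication flags: any qualifying fill inside the lookback window
    lookback = pd.Timedelta(days=int(round(criteria.drug_lookback_months * DAYS_PER_MONTH)))
    dc = drug_covariates.copy()
    if len(dc):
        _require_columns(dc, ("patient_id", "drug_group", "date"), "drug_covariates")
        dc["date"] = _as_datetime(dc["date"])
        dc = dc.merge(baseline.rename("baseline"), left_on="patient_id",
                      right_index=True, how="inner")
        dc = dc[(dc["date"] <= dc["baseline"]) & (dc["date"] > dc["baseline"] - lookback)]
    for name in DRUG_FLAGS:
        hit = dc[dc["drug_group"] == name]["patient_id"].unique() if len(dc) else []
        cov[name] = cov.index.isin(hit).astype(int)

    if cov.isna().any().any():
        raise ConfigurationError("covariate assembly left absent values")
    return cov


def covariate_design_matrix(cov: pd.DataFrame,
                            include: list[str] | None = None
                            ) -> tuple[np.ndarray, list[str]]:
    """Main-effects design matrix (no intercept column) from the
    baseline covariate frame: continuous terms as-is (age centred,
    log days from diagnosis), dummy indicators for every non-reference
    categorical level present, and the 0/1 flags."""
    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name, values):
        cols.append(np.asarray(values, dtype=float))
        names.append(name)

    wanted = set(include) if include is not None else None

    def want(name):
        return wanted is None or name in wanted

    if want("age"):
        # linear + quadratic so the treatment model can balance both the
        # location and the spread of age between arms
        add("age", cov["age"] - 67.0)
        add("age_sq", ((cov["age"] - 67.0) / 10.0) ** 2)
    if want("time_from_diagnosis"):
        lt = np.log(np.clip(cov["time_from_diagnosis_days"], 1.0, None))
        add("log_time_from_diagnosis", lt)
        add("log_time_from_diagnosis_sq", (lt - 4.5) ** 2)
    year_levels = sorted(cov["baseline_year"].unique())
    if want("baseline_year"):
        for lev in year_levels[1:]:
            add(f"baseline_year:{lev}", cov["baseline_year"] == lev)
    for name, levels in CATEGORICAL_LEVELS.items():
        if not want(name):
            continue
        present = [l for l in levels + ["missing"] if l in set(cov[name])]
        for lev in present[1:]:
            add(f"{name}:{lev}", cov[name] == lev)
    for name in BINARY_COVARIATES:
        if want(name):
            add(name, cov[name])
    X = np.column_stack(cols) if cols else np.empty((len(cov), 0))
    return X, names
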