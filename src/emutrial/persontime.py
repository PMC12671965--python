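"""Discrete person-period expansion.

Follow-up is cut into consecutive 1-month intervals (30.4375 days) from
baseline; interval k covers days [k*30.4375, (k+1)*30.4375). Each
eligible patient contributes one record per interval until the first of
death (event recorded in the containing interval), emigration (the
partial interval is dropped), 60 intervals, or the administrative end
(the partial interval is kept, mirroring how a registry extract closes).
The per-protocol view additionally censors at the first protocol
deviation; the deviation interval itself is returned separately with
C_k = 1 so the censoring models can be fitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COMORBIDITY_FLAGS, DRUG_FLAGS, _as_datetime
from .config import DAYS_PER_MONTH, FOLLOWUP_MONTHS
from .errors import DataError

__all__ = ["expand_person_periods", "attach_time_varying", "censor_at_deviation",
           "TIME_VARYING_CONDITIONS", "TIME_VARYING_DRUGS"]

TIME_VARYING_CONDITIONS = COMORBIDITY_FLAGS + ("chronic_kidney_disease",)
TIME_VARYING_DRUGS = DRUG_FLAGS


def expand_person_periods(
    eligible: pd.DataFrame,
    interval_days: float = DAYS_PER_MONTH,
    max_months: int = FOLLOWUP_MONTHS,
) -> pd.DataFrame:
    """One record per patient-interval with the death indicator Y_k.

    Requires ``baseline_date``, ``followup_end_date`` and ``end_reason``
    (from :func:`emutrial.cohort.apply_eligibility`).
    """
    el = eligible
    baseline = _as_datetime(el["baseline_date"])
    end = _as_datetime(el["followup_end_date"])
    reason = el["end_reason"].astype(str).to_numpy()
    days = (end - baseline).dt.days.to_numpy(float)
    if np.any(days < 0):
        raise DataError("follow-up end before baseline")

    k_end = np.floor(days / interval_days).astype(int)  # interval containing end
    n_int = np.where(
        reason == "death", k_end + 1,
        np.where(reason == "emigration", k_end,            # partial interval dropped
                 np.ceil(days / interval_days).astype(int)))  # admin / 5 years
    n_int = np.clip(n_int, 0, max_months)

    pid = np.repeat(el["patient_id"].to_numpy(), n_int)
    idx = np.repeat(np.arange(len(el)), n_int)
    k = np.concatenate([np.arange(m) for m in n_int]) if len(el) else np.empty(0, int)
    y = np.zeros(pid.size, dtype=np.int8)
    is_death_row = (np.repeat(reason == "death", n_int)
                    & (k == np.repeat(np.where(reason == "death", k_end, -1), n_int)))
    y[is_death_row] = 1

    out = pd.DataFrame({"patient_id": pid, "row": idx, "k": k, "event": y})
    out["strategy"] = el["strategy"].to_numpy()[idx] if "strategy" in el else None
    out["admin_or_emigration_censored"] = np.repeat(
        np.isin(reason, ("admin_end", "emigration")).astype(np.int8), n_int) \
        * (out.groupby("patient_id")["k"].transform("max").to_numpy() == out["k"].to_numpy())
    return out


def _interval_of(dates: pd.Series, baseline: pd.Series,
                 interval_days: float = DAYS_PER_MONTH) -> np.ndarray:
    days = (dates.to_numpy("datetime64[D]").astype("float64")
            - baseline.to_numpy("datetime64[D]").astype("float64"))
    return np.floor(days / interval_days)


def attach_time_varying(
    person_periods: pd.DataFrame,
    eligible: pd.DataFrame,
    diagnoses: pd.DataFrame,
    drug_covariates: pd.DataFrame,
    drug_window_months: int = 6,
) -> pd.DataFrame:
    """Add time-varying covariate flags L_k to the person-period table.

    Diagnosis flags switch on in the interval containing the first
    qualifying record and stay on; drug flags are current for
    ``drug_window_months`` intervals starting at the interval of each
    fill (a fill in month m keeps the flag on for k in [m, m+window)).
    """
    pp = person_periods.copy()
    el = eligible.set_index("patient_id")
    baseline = _as_datetime(el["baseline_date"])
    pos = pd.Series(np.arange(len(el)), index=el.index)
    row = pos.reindex(pp["patient_id"]).to_numpy()
    k = pp["k"].to_numpy()

    for cond in TIME_VARYING_CONDITIONS:
        sub = diagnoses[diagnoses["condition"] == cond] if len(diagnoses) else diagnoses
        first = np.full(len(el), np.inf)
        if len(sub):
            sub = sub[sub["patient_id"].isin(el.index)]
            if len(sub):
                m = _interval_of(_as_datetime(sub["date"]),
                                 baseline.reindex(sub["patient_id"]))
                onset = pd.Series(m).groupby(sub["patient_id"].to_numpy()).min()
                first[pos.reindex(onset.index).to_numpy()] = onset.to_numpy()
        pp[f"tv_{cond}"] = (k >= first[row]).astype(np.int8)

    for grp in TIME_VARYING_DRUGS:
        sub = drug_covariates[drug_covariates["drug_group"] == grp] \
            if len(drug_covariates) else drug_covariates
        flag = np.zeros(len(pp), dtype=np.int8)
        if len(sub):
            sub = sub[sub["patient_id"].isin(el.index)]
            if len(sub):
                m = _interval_of(_as_datetime(sub["date"]),
                                 baseline.reindex(sub["patient_id"]))
                fill_row = pos.reindex(sub["patient_id"]).to_numpy()
                # per (patient, interval) currency via a coverage matrix in
                # interval space: month m covers [m, m + window)
                lo = np.maximum(m, -10_000).astype(int)
                cover = np.zeros((len(el), FOLLOWUP_MONTHS + 1), dtype=np.int32)
                a = np.clip(lo, 0, FOLLOWUP_MONTHS)
                b = np.clip(lo + drug_window_months, 0, FOLLOWUP_MONTHS)
                valid = b > a
                np.add.at(cover, (fill_row[valid], a[valid]), 1)
                np.add.at(cover, (fill_row[valid], b[valid]), -1)
                active = np.cumsum(cover[:, :-1], axis=1) > 0
                flag = active[row, k].astype(np.int8)
        pp[f"tv_{grp}"] = flag
    return pp


def censor_at_deviation(
    person_periods: pd.DataFrame,
    episodes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protocol censoring at the first protocol deviation.

    Returns ``(per_protocol, censor_fit)``:

    * ``per_protocol`` — records strictly before the deviation interval
      (the ITT table is left untouched);
    * ``censor_fit`` — the at-risk records for the censoring models: the
      retained records with ``deviates = 0`` plus, when the deviation
      interval is still inside the patient's ITT follow-up, that
      interval's record with ``deviates = 1``. Death and deviation in
      the same interval counts the death (the event is kept, the record
      is not censored).
    """
    ep = episodes.set_index("patient_id")["deviation_interval"]
    k_dev = ep.reindex(person_periods["patient_id"]).to_numpy(dtype="float64",
                                                              na_value=np.inf)
    if np.any(k_dev <= 0):
        raise DataError("deviation in interval 0 violates the episode invariant")
    k = person_periods["k"].to_numpy()
    y = person_periods["event"].to_numpy()

    before = k < k_dev
    at_dev = k == k_dev
    death_wins = at_dev & (y == 1)     # death in the deviation interval wins
    pp = person_periods[before | death_wins].copy()
    pp["deviates"] = 0

    cf = person_periods[before | at_dev].copy()
    cf["deviates"] = (at_dev & (y == 0))[before | at_dev].astype(np.int8)
    return pp, cf
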