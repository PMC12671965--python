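"""End-to-end assembly: tables -> cohort -> person-time -> estimate.

`build_dataset` runs every deterministic, patient-level step once
(eligibility, covariate assembly, episode construction, person-period
expansion, per-protocol censoring) and stores flat arrays keyed by
patient position. `estimate` then performs one analysis — weight
models plus outcome model — on those arrays. Because patient
resampling enters purely as per-patient frequency weights, bootstrap
replicates re-fit *all* models (treatment, censoring, outcome) without
re-running the expansion, which is what makes 1000-replicate bootstraps
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .cohort import (AI_CLASS, apply_eligibility, assemble_baseline_covariates,
                     covariate_design_matrix)
from .config import FOLLOWUP_MONTHS, AnalysisConfig, EligibilityCriteria
from .errors import ConfigurationError, DataError
from .exposure import episodes_for_cohort
from .outcome import (EffectEstimates, PooledLogisticFit, RiskCurve,
                      effect_measures, fit_pooled_logistic,
                      standardized_risk_curve)
from .persontime import (attach_time_varying, censor_at_deviation,
                         expand_person_periods)
from .weights import combine_weights, fit_ipcw, fit_iptw

__all__ = ["AnalysisDataset", "build_dataset", "estimate", "SUBGROUPS"]

#: named baseline subgroup predicates (evaluated on the covariate frame)
SUBGROUPS = {
    "age_lt_65": lambda cov: cov["age"].to_numpy() < 65,
    "age_ge_65": lambda cov: cov["age"].to_numpy() >= 65,
    "chemotherapy": lambda cov: cov["chemotherapy"].to_numpy() == 1,
    "no_chemotherapy": lambda cov: cov["chemotherapy"].to_numpy() == 0,
    "opioid_or_antidepressant_users": lambda cov: (
        (cov["opioids"].to_numpy() == 1) | (cov["antidepressants"].to_numpy() == 1)),
    "opioid_or_antidepressant_nonusers": lambda cov: (
        (cov["opioids"].to_numpy() == 0) & (cov["antidepressants"].to_numpy() == 0)),
}


@dataclass
class AnalysisDataset:
    """Pre-expanded cohort ready for (repeated) estimation."""

    eligible: pd.DataFrame
    ledger: pd.DataFrame
    covariates: pd.DataFrame
    episodes: pd.DataFrame
    person_periods: pd.DataFrame          # ITT, with time-varying flags
    X_baseline: np.ndarray                # (n, p) design, patient order
    baseline_names: list[str]
    arm_ai: np.ndarray                    # (n,) bool
    any_missing: np.ndarray               # (n,) bool
    # ITT person-period arrays (patient-major, k ascending)
    pp_row: np.ndarray
    pp_k: np.ndarray
    pp_y: np.ndarray
    # censoring-model (at-risk) arrays; per-protocol rows are the
    # ``cf_dev == 0`` subset in identical order
    cf_row: np.ndarray
    cf_k: np.ndarray
    cf_y: np.ndarray
    cf_dev: np.ndarray
    cf_tv: np.ndarray                     # time-varying covariate rows
    tv_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.eligible)


def build_dataset(
    tables: dict[str, pd.DataFrame],
    criteria: EligibilityCriteria | None = None,
    admin_end: date = date(2015, 12, 31),
    grace_days: int = 60,
) -> AnalysisDataset:
    """Run the deterministic cohort pipeline on the four linked tables
    (keys: patients, dispensations, diagnoses, drug_covariates)."""
    criteria = criteria or EligibilityCriteria()
    for key in ("patients", "dispensations", "diagnoses", "drug_covariates"):
        if key not in tables:
            raise ConfigurationError(f"missing input table {key!r}")

    eligible, ledger = apply_eligibility(tables["patients"], tables["dispensations"],
                                         criteria, admin_end=admin_end)
    eligible = eligible.sort_values("patient_id", kind="stable").reset_index(drop=True)
    cov = assemble_baseline_covariates(eligible, tables["diagnoses"],
                                       tables["drug_covariates"], criteria)
    X, names = covariate_design_matrix(cov)
    episodes = episodes_for_cohort(eligible, tables["dispensations"], grace_days)

    pp = expand_person_periods(eligible)
    pp = attach_time_varying(pp, eligible, tables["diagnoses"],
                             tables["drug_covariates"],
                             drug_window_months=criteria.drug_lookback_months)
    _, cf = censor_at_deviation(pp, episodes)

    tv_cols = [c for c in cf.columns if c.startswith("tv_")]
    missing = np.zeros(len(eligible), dtype=bool)
    for col in cov.columns:
        if cov[col].dtype == object:
            missing |= (cov[col] == "missing").to_numpy()

    return AnalysisDataset(
        eligible=eligible, ledger=ledger, covariates=cov, episodes=episodes,
        person_periods=pp,
        X_baseline=X, baseline_names=names,
        arm_ai=(cov["strategy"] == AI_CLASS).to_numpy(),
        any_missing=missing,
        pp_row=pp["row"].to_numpy(), pp_k=pp["k"].to_numpy(np.int64),
        pp_y=pp["event"].to_numpy(np.float64),
        cf_row=cf["row"].to_numpy(), cf_k=cf["k"].to_numpy(np.int64),
        cf_y=cf["event"].to_numpy(np.float64),
        cf_dev=cf["deviates"].to_numpy(np.float64),
        cf_tv=cf[tv_cols].to_numpy(np.float64) if tv_cols else np.zeros((len(cf), 0)),
        tv_names=tv_cols,
    )


@dataclass
class EstimateResult:
    estimates: EffectEstimates
    curves: dict[str, RiskCurve]
    models: dict[str, PooledLogisticFit]
    weight_diagnostics: dict


def _patient_mask(ds: AnalysisDataset, config: AnalysisConfig) -> np.ndarray:
    mask = np.ones(ds.n, dtype=bool)
    if config.subgroup is not None:
        if config.subgroup not in SUBGROUPS:
            raise ConfigurationError(
                f"unknown subgroup {config.subgroup!r}; "
                f"known: {sorted(SUBGROUPS)}")
        mask &= SUBGROUPS[config.subgroup](ds.covariates)
    if config.missing_handling == "complete_case":
        mask &= ~ds.any_missing
    return mask


def estimate(ds: AnalysisDataset, config: AnalysisConfig,
             freq: np.ndarray | None = None,
             on_nonconvergence: str = "raise") -> EstimateResult:
    """One full analysis under `config`.

    `freq` are per-patient frequency weights (bootstrap multiplicities);
    weight models and outcome models are all re-fitted under them.
    Subgroup restriction and complete-case filtering zero patients out,
    so weight models are re-estimated inside the restricted cohort.
    """
    replicate = freq is not None
    pfreq = np.ones(ds.n) if freq is None else np.asarray(freq, dtype=float)
    pfreq = pfreq * _patient_mask(ds, config)
    if pfreq.sum() == 0:
        raise DataError("analysis cohort is empty after restriction")

    a_pat = ds.arm_ai.astype(float)
    diagnostics: dict = {}

    # ---- treatment weights
    if config.adjustment == "iptw":
        iptw = fit_iptw(ds.X_baseline, a_pat, stabilize=config.stabilize_iptw,
                        truncate_pct=config.truncate_pct, freq_weights=pfreq,
                        column_names=ds.baseline_names,
                        compute_diagnostics=not replicate)
        w_pat = iptw.weights
        diagnostics["iptw"] = iptw.diagnostics
    else:
        w_pat = np.ones(ds.n)

    # ---- person-period rows for the requested contrast
    if config.contrast == "itt":
        row, k, y = ds.pp_row, ds.pp_k, ds.pp_y
        w_row = w_pat[row] * pfreq[row]
    else:
        keep = ds.cf_dev == 0
        row, k, y = ds.cf_row[keep], ds.cf_k[keep], ds.cf_y[keep]
        if config.use_ipcw and config.adjustment in ("iptw", "none"):
            X_cf = np.column_stack([ds.X_baseline[ds.cf_row], ds.cf_tv])
            ipcw = fit_ipcw(ds.cf_row, ds.cf_k, ds.cf_dev, ds.arm_ai[ds.cf_row],
                            X_cf, spline=config.spline,
                            stabilize=config.stabilize_ipcw,
                            freq_weights=pfreq[ds.cf_row],
                            column_names=ds.baseline_names + ds.tv_names)
            w_c = ipcw.weights[keep]
            diagnostics["ipcw"] = ipcw.diagnostics
        else:
            w_c = np.ones(int(keep.sum()))
        w_row, comb_diag = combine_weights(w_pat[row] * pfreq[row], w_c,
                                           compute_diagnostics=not replicate)
        diagnostics["combined"] = comb_diag
    if config.contrast == "itt":
        w_row, comb_diag = combine_weights(w_row, None,
                                           compute_diagnostics=not replicate)
        diagnostics["combined"] = comb_diag

    a_row = a_pat[row]

    # ---- outcome models
    if config.adjustment == "covariate_in_model":
        X_cov = ds.X_baseline[row]
        kwargs = dict(X_cov=X_cov, covariate_names=tuple(ds.baseline_names))
    else:
        kwargs = {}
    model_i = fit_pooled_logistic(k, a_row, y, w_row, spline=config.spline,
                                  interaction=True,
                                  on_nonconvergence=on_nonconvergence, **kwargs)
    model_h = fit_pooled_logistic(k, a_row, y, w_row, spline=config.spline,
                                  interaction=False,
                                  on_nonconvergence=on_nonconvergence, **kwargs)
    model_i.max_k = FOLLOWUP_MONTHS
    model_h.max_k = FOLLOWUP_MONTHS

    if config.adjustment == "covariate_in_model":
        sel = pfreq > 0
        std = dict(X_pop=ds.X_baseline[sel], pop_weights=pfreq[sel])
    else:
        std = {}
    curve_ai = standardized_risk_curve(model_i, 1, **std)
    curve_tam = standardized_risk_curve(model_i, 0, **std)
    est = effect_measures(curve_ai, curve_tam, model_h)

    return EstimateResult(estimates=est,
                          curves={"aromatase_inhibitor": curve_ai,
                                  "tamoxifen": curve_tam},
                          models={"interaction": model_i, "no_interaction": model_h},
                          weight_diagnostics=diagnostics)
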