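"""Inverse-probability weights.

Treatment weights (IPTW) re-weight the cohort so the two strategy
groups have the same baseline covariate distribution as the combined
cohort: each patient gets numerator/denominator with denominator the
fitted probability of her *own* strategy given baseline covariates,
and numerator 1 (unstabilized) or the marginal strategy probability
(stabilized, the default).

Censoring weights (IPCW) correct the selection induced by censoring at
protocol deviation: per strategy arm, a pooled logistic model of
deviating in interval k on baseline covariates, time-varying covariates
and a spline of k gives interval-specific probabilities of remaining
uncensored, and the weight at interval k is the cumulative product of
their inverses over intervals up to and including k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._glm import LogisticFit, check_overlap, fit_weighted_logistic
from .errors import DataError, FitError
from .splines import SplineSpec, rcs_basis

__all__ = ["IptwResult", "IpcwResult", "fit_iptw", "fit_ipcw", "combine_weights"]


@dataclass
class IptwResult:
    weights: np.ndarray          # per patient
    p_treatment: np.ndarray      # fitted P(A = AI | L)
    fit: LogisticFit | None
    stabilized: bool
    truncated: np.ndarray        # per-patient flag
    diagnostics: dict = field(default_factory=dict)


@dataclass
class IpcwResult:
    weights: np.ndarray          # per supplied at-risk record (cumulative)
    fits: dict
    stabilized: bool
    diagnostics: dict = field(default_factory=dict)


def _summary(w: np.ndarray) -> dict:
    if w.size == 0:
        return {"n": 0}
    return {"n": int(w.size), "mean": float(w.mean()), "max": float(w.max()),
            "p1": float(np.percentile(w, 1)), "p99": float(np.percentile(w, 99))}


def fit_iptw(
    X: np.ndarray,
    treated: np.ndarray,
    *,
    stabilize: bool = True,
    truncate_pct: float | None = None,
    freq_weights: np.ndarray | None = None,
    column_names: list[str] | None = None,
    compute_diagnostics: bool = True,
) -> IptwResult:
    """Baseline inverse-probability-of-treatment weights.

    `X` is the main-effects covariate matrix *without* intercept (an
    intercept column is added); an empty matrix gives the null model,
    under which every stabilized weight is exactly 1.
    """
    treated = np.asarray(treated).astype(float)
    n = treated.size
    Xd = np.column_stack([np.ones(n), np.asarray(X, dtype=float)]) \
        if X is not None and np.size(X) else np.ones((n, 1))
    names = tuple(["intercept"] + list(column_names or [])) \
        if Xd.shape[1] > 1 else ("intercept",)
    fit = fit_weighted_logistic(Xd, treated, freq_weights, column_names=names)
    p = fit.predict_proba(Xd)
    denom = np.where(treated == 1, p, 1.0 - p)
    # positivity check: a fitted strategy probability of 0 or 1 to
    # machine precision means some covariate pattern only ever receives
    # one strategy
    in_sample = np.ones(n, bool) if freq_weights is None \
        else np.asarray(freq_weights) > 0
    check_overlap(np.where(in_sample, p, 0.5))
    if stabilize:
        marg = float(np.average(treated, weights=freq_weights))
        numer = np.where(treated == 1, marg, 1.0 - marg)
    else:
        numer = np.ones(n)
    w = numer / denom

    truncated = np.zeros(n, dtype=bool)
    if truncate_pct is not None:
        lo, hi = np.percentile(w, [truncate_pct, 100.0 - truncate_pct])
        truncated = (w < lo) | (w > hi)
        w = np.clip(w, lo, hi)

    diag = {"stabilized": stabilize, "n_truncated": int(truncated.sum())}
    if compute_diagnostics:
        diag["weights"] = _summary(w)
    return IptwResult(weights=w, p_treatment=p, fit=fit, stabilized=stabilize,
                      truncated=truncated, diagnostics=diag)


def fit_ipcw(
    patient: np.ndarray,
    k: np.ndarray,
    deviates: np.ndarray,
    treated: np.ndarray,
    X_rows: np.ndarray,
    *,
    spline: SplineSpec | None = None,
    stabilize: bool = False,
    freq_weights: np.ndarray | None = None,
    column_names: list[str] | None = None,
) -> IpcwResult:
    """Cumulative inverse-probability-of-censoring weights.

    Inputs are the *at-risk* records of the per-protocol view — one row
    per patient-interval the patient entered uncensored, with
    ``deviates`` = 1 on the interval of her protocol deviation. Rows
    must be grouped by patient with k increasing within patient. A
    separate censoring model is fitted per strategy arm; time enters
    through the restricted cubic spline. With ``stabilize``, the
    numerator is the analogous per-arm model with time only.
    """
    spline = spline or SplineSpec()
    patient = np.asarray(patient)
    k = np.asarray(k, dtype=float)
    deviates = np.asarray(deviates, dtype=float)
    treated = np.asarray(treated).astype(bool)
    n = patient.size
    if n and np.any((patient[1:] == patient[:-1]) & (np.diff(k) <= 0)):
        raise DataError("at-risk records must be sorted by patient and interval")

    tb = rcs_basis(k, spline)
    Xd = np.column_stack([np.ones(n), np.asarray(X_rows, dtype=float), tb])
    names = tuple(["intercept"] + list(column_names or
                                       [f"x{i}" for i in range(np.shape(X_rows)[1])])
                  + spline.column_names())
    w = freq_weights if freq_weights is not None else np.ones(n)

    log_factor = np.zeros(n)
    fits = {}
    for arm, label in ((True, "aromatase_inhibitor"), (False, "tamoxifen")):
        m = treated == arm
        if not m.any():
            continue
        if deviates[m].sum() == 0:
            # nobody deviates in this arm: weights are exactly 1
            fits[label] = None
            continue
        try:
            fit = fit_weighted_logistic(Xd[m], deviates[m], w[m], column_names=names)
        except FitError as exc:
            raise FitError(f"censoring model failed in arm {label}: {exc}") from exc
        p_dev = fit.predict_proba(Xd[m])
        if np.any(p_dev > 1 - 1e-10):
            raise FitError(f"censoring model in arm {label} predicts certain "
                           "censoring (separation)")
        log_factor[m] = -np.log1p(-p_dev)
        fits[label] = fit
        if stabilize:
            Xt = np.column_stack([np.ones(int(m.sum())), tb[m]])
            fit_num = fit_weighted_logistic(Xt, deviates[m], w[m])
            log_factor[m] += np.log1p(-fit_num.predict_proba(Xt))
            fits[label + "_numerator"] = fit_num

    # cumulative product within patient (rows already ordered)
    if n:
        cum = np.cumsum(log_factor)
        starts = np.flatnonzero(np.r_[True, patient[1:] != patient[:-1]])
        offset = np.repeat(np.r_[0.0, cum[starts[1:] - 1]],
                           np.diff(np.r_[starts, n]))
        weights = np.exp(cum - offset)
    else:
        weights = np.zeros(0)

    return IpcwResult(weights=weights, fits=fits, stabilized=stabilize,
                      diagnostics={"weights": _summary(weights)})


def combine_weights(iptw_per_row: np.ndarray, ipcw_per_row: np.ndarray | None,
                    compute_diagnostics: bool = True) -> tuple[np.ndarray, dict]:
    """Elementwise total weight W^A x W^C with summary diagnostics."""
    a = np.asarray(iptw_per_row, dtype=float)
    if ipcw_per_row is None:
        total = a.copy()
    else:
        c = np.asarray(ipcw_per_row, dtype=float)
        if c.shape != a.shape:
            raise DataError("treatment and censoring weights are misaligned")
        total = a * c
    return total, ({"total": _summary(total)} if compute_diagnostics else {})
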