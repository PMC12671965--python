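"""Nonparametric bootstrap, subgroup and sensitivity runners.

Confidence intervals are percentile bootstrap over patient resamples:
patients (not person-periods) are drawn with replacement and *every*
model — treatment weights, censoring weights, outcome — is re-fitted
inside each replicate, so the intervals reflect weight-estimation
uncertainty. Resampling enters as per-patient frequency weights on the
pre-expanded dataset (see :mod:`emutrial.pipeline`). Replicates whose
fits fail to converge are dropped and counted; more than a configurable
fraction of failures aborts the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import DataError, EmutrialError, FitError
from .outcome import EffectEstimates
from .pipeline import SUBGROUPS, AnalysisDataset, EstimateResult, estimate

__all__ = ["BootstrapResult", "bootstrap_cis", "percentile_ci",
           "resample_frequencies", "run_subgroup", "run_sensitivity"]

_MEASURES = ("risk_ai_5y", "risk_tam_5y", "rd", "rr", "avg_hr")


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval (linear interpolation)."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        return (float("nan"), float("nan"))
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def resample_frequencies(rng: np.random.Generator, n: int) -> np.ndarray:
    """Multiplicity vector of one with-replacement resample of n patients."""
    idx = rng.integers(0, n, size=n)
    return np.bincount(idx, minlength=n).astype(float)


@dataclass
class BootstrapResult:
    point: EstimateResult
    replicates: pd.DataFrame          # one row per successful replicate
    n_requested: int
    n_failed: int
    ci: dict = field(default_factory=dict)

    @property
    def estimates(self) -> EffectEstimates:
        return self.point.estimates


def bootstrap_cis(ds: AnalysisDataset, config: AnalysisConfig,
                  level: float = 0.95) -> BootstrapResult:
    """Point estimate plus percentile bootstrap CIs under `config`.

    Deterministic under ``config.seed``; the same seed reproduces the
    same resamples and hence byte-identical intervals.
    """
    point = estimate(ds, config)
    rng = np.random.default_rng(config.seed)
    rows, n_failed = [], 0
    for _ in range(int(config.n_bootstrap)):
        freq = resample_frequencies(rng, ds.n)
        try:
            rep = estimate(ds, config, freq=freq, on_nonconvergence="raise")
        except (FitError, DataError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        d = rep.estimates.as_dict()
        rows.append([d[m] if d[m] is not None else np.nan for m in _MEASURES])

    if config.n_bootstrap and n_failed > config.max_replicate_failure * config.n_bootstrap:
        raise EmutrialError(
            f"{n_failed}/{config.n_bootstrap} bootstrap replicates failed "
            f"(> {100 * config.max_replicate_failure:.0f}%); the analysis is "
            "too unstable at this sample size")

    reps = pd.DataFrame(rows, columns=list(_MEASURES))
    ci = {m: percentile_ci(reps[m].to_numpy(), level) for m in _MEASURES} \
        if len(reps) else {}
    point.estimates.ci = ci
    return BootstrapResult(point=point, replicates=reps,
                           n_requested=int(config.n_bootstrap),
                           n_failed=n_failed, ci=ci)


def run_subgroup(ds: AnalysisDataset, subgroup: str,
                 config: AnalysisConfig) -> BootstrapResult:
    """Re-run the full analysis restricted to a named baseline subgroup.

    Weight models are re-fitted *within* the subgroup — full-cohort
    weights are never reused.
    """
    if subgroup not in SUBGROUPS:
        raise DataError(f"unknown subgroup {subgroup!r}; known: {sorted(SUBGROUPS)}")
    return bootstrap_cis(ds, replace(config, subgroup=subgroup))


def run_sensitivity(ds: AnalysisDataset, config: AnalysisConfig) -> dict[str, BootstrapResult]:
    """The two pre-specified sensitivity analyses.

    (1) covariate adjustment in the pooled logistic models (with
    g-formula standardization) instead of IP weighting; (2) complete
    cases only, dropping every patient with any "missing" category.
    """
    out = {}
    out["covariate_adjusted"] = bootstrap_cis(
        ds, replace(config, adjustment="covariate_in_model"))
    out["complete_case"] = bootstrap_cis(
        ds, replace(config, missing_handling="complete_case"))
    return out
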