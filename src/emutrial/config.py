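"""Scenario and analysis configuration objects.

A :class:`ScenarioConfig` fully determines a synthetic linked-registry
dataset (together with a seed), and an :class:`AnalysisConfig` fully
determines one analysis of such data (contrast, adjustment, subgroup,
missing-data handling, bootstrap settings). Both round-trip through
plain YAML mappings so scenario files can be version-controlled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import yaml

from .calibration import COHORT_PROFILE, arm_share, default_treatment_coefs
from .errors import ConfigurationError
from .splines import SplineSpec

__all__ = [
    "DAYS_PER_MONTH",
    "FOLLOWUP_MONTHS",
    "NINE_MONTHS_DAYS",
    "DDD_MG",
    "AI_DRUGS",
    "AdherenceParams",
    "ScenarioConfig",
    "AnalysisConfig",
    "EligibilityCriteria",
    "load_scenario",
    "save_scenario",
]

#: length of the discrete follow-up interval, in days (one mean month)
DAYS_PER_MONTH = 30.4375
#: administrative follow-up horizon, in intervals
FOLLOWUP_MONTHS = 60
#: "within 9 months of surgery", as a documented whole-day constant
NINE_MONTHS_DAYS = 274

#: WHO defined daily dose, mg/day, per endocrine drug (editable)
DDD_MG = {
    "letrozole": 2.5,
    "anastrozole": 1.0,
    "exemestane": 25.0,
    "tamoxifen": 20.0,
}
AI_DRUGS = ("letrozole", "anastrozole", "exemestane")
ALL_DRUGS = AI_DRUGS + ("tamoxifen",)


def _check_prob(x: float, what: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ConfigurationError(f"{what} must be in [0, 1], got {x}")
    return x


@dataclass
class AdherenceParams:
    """Drives stochastic gaps, permanent stops and switches in the
    dispensation streams.

    discontinuation_hazard : per-arm probability per 1-month interval of
        deciding to stop refilling the assigned drug class.
    switch_prob : probability that a discontinuation is a switch to the
        other drug class (at the next scheduled fill date) rather than a
        permanent stop.
    discontinuation_coefs : optional log-odds coefficients of baseline
        covariates on the per-interval discontinuation hazard; an empty
        map makes nonadherence completely independent of covariates.
    """

    discontinuation_hazard: dict = field(
        default_factory=lambda: {"aromatase_inhibitor": 0.009, "tamoxifen": 0.0095}
    )
    switch_prob: float = 0.30
    discontinuation_coefs: dict = field(default_factory=dict)

    def validate(self) -> None:
        for arm, h in self.discontinuation_hazard.items():
            _check_prob(h, f"discontinuation_hazard[{arm}]")
        _check_prob(self.switch_prob, "switch_prob")


def _default_hazard_coefs() -> dict:
    # per-interval log-odds of death on baseline covariates; age in years
    # (centred at 67 internally), strongly age-driven as for all-cause
    # mortality, with comorbidity/treatment-history gradients
    return {
        "intercept": -7.50,
        "age_c": 0.075,
        "stage:2": 0.45,
        "stage:3": 1.10,
        "grade:3": 0.45,
        "n_class:N1plus": 0.35,
        "chemotherapy": 0.25,
        "cardiovascular_disease": 0.45,
        "diabetes": 0.35,
        "cerebrovascular_disease": 0.50,
        "copd": 0.50,
        "opioids": 0.55,
        "antidepressants": 0.35,
        "anticoagulants": 0.25,
        "employment:not_employed": 0.25,
    }


@dataclass
class ScenarioConfig:
    """All parameters of the synthetic linked-registry data-generating
    process. Defaults emulate the published 2009-2015 Swedish cohort
    profile (see :mod:`emutrial.calibration`)."""

    n_patients: int = 12536
    seed: int = 0
    #: log-odds coefficients of the first-fill (treatment-choice) model;
    #: None -> profile-implied log-likelihood-ratio coefficients.
    #: May contain an explicit "intercept"; otherwise the intercept is
    #: solved in-sample to hit `treated_share`.
    treatment_model_coefs: Optional[dict] = None
    treated_share: float = arm_share()
    #: per-interval log-odds of death; must contain "intercept"
    hazard_model_coefs: dict = field(default_factory=_default_hazard_coefs)
    #: conditional effect of aromatase inhibitor vs tamoxifen on the
    #: interval death odds (log odds ratio)
    true_treatment_log_or: float = -0.0943  # log(0.91)
    #: optional effect modification: covariate -> additional treatment
    #: log odds ratio when the (binary) covariate is 1
    effect_modifier_coefs: dict = field(default_factory=dict)
    adherence_params: AdherenceParams = field(default_factory=AdherenceParams)
    emigration_rate: float = 0.0004
    enrollment_start: date = date(2009, 8, 1)
    enrollment_end: date = date(2015, 12, 31)
    admin_end: date = date(2015, 12, 31)
    #: fill length distribution: days of supply -> probability
    dispensation_supply_days: dict = field(
        default_factory=lambda: {30: 0.15, 90: 0.55, 100: 0.30}
    )
    #: market split among the three aromatase inhibitors at first fill
    ai_drug_split: dict = field(
        default_factory=lambda: {"letrozole": 0.55, "anastrozole": 0.35,
                                 "exemestane": 0.10}
    )
    #: Gaussian-copula equicorrelation among comorbidity/co-medication
    #: flags *within* latent profile class (marginals preserved); the
    #: latent class itself already induces positive dependence.
    comorbidity_correlation: float = 0.0
    #: monthly post-baseline incidence of new comorbidity diagnoses and
    #: of new co-medication use (feeds the time-varying covariates)
    comorbidity_onset_rate: float = 0.0015
    drug_initiation_rate: float = 0.002
    #: arm-specific covariate profile; defaults to the published cohort
    profile: dict = field(default_factory=lambda: COHORT_PROFILE)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if int(self.n_patients) < 0:
            raise ConfigurationError("n_patients must be >= 0")
        _check_prob(self.treated_share, "treated_share")
        _check_prob(self.emigration_rate, "emigration_rate")
        _check_prob(self.comorbidity_correlation, "comorbidity_correlation")
        _check_prob(self.comorbidity_onset_rate, "comorbidity_onset_rate")
        _check_prob(self.drug_initiation_rate, "drug_initiation_rate")
        if self.enrollment_start > self.enrollment_end:
            raise ConfigurationError("empty enrollment window")
        if self.enrollment_end > self.admin_end:
            raise ConfigurationError("enrollment window must end by admin_end")
        if "intercept" not in self.hazard_model_coefs:
            raise ConfigurationError("hazard_model_coefs needs an 'intercept'")
        supply = self.dispensation_supply_days
        if not supply or abs(sum(supply.values()) - 1.0) > 1e-9:
            raise ConfigurationError("dispensation_supply_days must sum to 1")
        if any(int(d) < 1 for d in supply):
            raise ConfigurationError("supply lengths must be >= 1 day")
        for d in self.ai_drug_split:
            if d not in AI_DRUGS:
                raise ConfigurationError(f"unknown aromatase inhibitor {d!r}")
        if abs(sum(self.ai_drug_split.values()) - 1.0) > 1e-9:
            raise ConfigurationError("ai_drug_split must sum to 1")
        self.adherence_params.validate()

    def resolved_treatment_coefs(self) -> dict:
        if self.treatment_model_coefs is None:
            return default_treatment_coefs(self.profile)
        return dict(self.treatment_model_coefs)


@dataclass
class EligibilityCriteria:
    """Emulation eligibility rules and lookback windows (whole days)."""

    min_age: float = 40.0
    postmenopausal_min_age: float = 50.0
    menopause_flag_column: Optional[str] = None
    max_surgery_to_dispensation_days: int = NINE_MONTHS_DAYS
    require_clear_margins: bool = True
    require_hr_positive: bool = True
    allowed_stages: tuple = ("1", "2", "3")
    #: patient-table 0/1 columns whose value 1 excludes the patient
    exclusion_flag_columns: tuple = ("bilateral_cancer", "prior_malignancy")
    #: lookback for co-medication baseline flags and for the time-varying
    #: drug "currency" window, in months of the discrete clock
    drug_lookback_months: int = 6
    enrollment_start: date = date(2009, 8, 1)
    enrollment_end: date = date(2015, 12, 31)


@dataclass
class AnalysisConfig:
    """One analysis of a cohort: estimand, adjustment and inference."""

    contrast: str = "itt"                   # "itt" | "per_protocol"
    adjustment: str = "iptw"                # "iptw" | "covariate_in_model" | "none"
    subgroup: Optional[str] = None          # named baseline predicate
    missing_handling: str = "category"      # "category" | "complete_case"
    n_bootstrap: int = 1000
    seed: int = 0
    spline: SplineSpec = field(default_factory=SplineSpec)
    stabilize_iptw: bool = True
    truncate_pct: Optional[float] = None    # e.g. 1.0 for 1/99 truncation
    stabilize_ipcw: bool = False
    #: disable censoring weights in the per-protocol analysis (naive
    #: per-protocol estimate; used for diagnostics and null tests)
    use_ipcw: bool = True
    grace_days: int = 60
    max_replicate_failure: float = 0.10

    def __post_init__(self):
        if self.contrast not in ("itt", "per_protocol"):
            raise ConfigurationError(f"unknown contrast {self.contrast!r}")
        if self.adjustment not in ("iptw", "covariate_in_model", "none"):
            raise ConfigurationError(f"unknown adjustment {self.adjustment!r}")
        if self.missing_handling not in ("category", "complete_case"):
            raise ConfigurationError(
                f"unknown missing_handling {self.missing_handling!r}")
        if int(self.n_bootstrap) < 0:
            raise ConfigurationError("n_bootstrap must be >= 0")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def save_scenario(config: ScenarioConfig, path) -> None:
    payload = _to_plain(config)
    payload.pop("profile", None)  # the profile constant is not serialized
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _parse_date(v):
    return v if isinstance(v, date) else date.fromisoformat(str(v))


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "adherence_params" in raw:
        raw["adherence_params"] = AdherenceParams(**raw["adherence_params"])
    for key in ("enrollment_start", "enrollment_end", "admin_end"):
        if key in raw:
            raw[key] = _parse_date(raw[key])
    if "dispensation_supply_days" in raw:
        raw["dispensation_supply_days"] = {
            int(k): float(v) for k, v in raw["dispensation_supply_days"].items()}
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    return ScenarioConfig(**raw)
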