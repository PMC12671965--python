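"""Synthetic linked-registry generator with counterfactual truth.

Generates the four registry-style tables the analysis consumes —
patients, dispensations, diagnoses, drug co-medications — with the
statistical structure the estimators assume:

* confounded treatment choice (first endocrine fill chosen by a logistic
  model on baseline covariates; defaults calibrated to the published
  2009-2015 Swedish cohort profile, see :mod:`emutrial.calibration`);
* a discrete-time death hazard (1-month clock, 30.4375 days) that is
  logistic in baseline covariates, the currently taken drug class and a
  known conditional treatment effect;
* pharmacy fill streams with refill jitter, stochastic permanent stops
  and class switches, so the 60-day-gap episode logic has realistic
  work to do;
* independent emigration, and administrative end of follow-up.

Because the death hazard given covariates and sustained treatment is
constant over follow-up, the counterfactual 5-year risk of each patient
has the closed form 1 - (1 - p_a(L))^60, and the population truth
(`true_counterfactual_risks`) averages that over a fresh draw of the
eligible population — the oracle every parameter-recovery test uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .calibration import categorical_probs, binary_prevalences
from .config import (AI_DRUGS, DAYS_PER_MONTH, DDD_MG, FOLLOWUP_MONTHS,
                     ScenarioConfig)
from .errors import ConfigurationError

__all__ = [
    "PopulationState",
    "SyntheticRegistry",
    "SyntheticTruth",
    "generate_population",
    "generate_dispensations",
    "generate_outcomes",
    "simulate_registry",
    "true_counterfactual_risks",
]

_EPOCH = np.datetime64("1970-01-01", "D")

COMORBIDITIES = ("cerebrovascular_disease", "diabetes", "copd",
                 "cardiovascular_disease", "chronic_kidney_disease")
DRUG_GROUPS = ("diabetes_drugs", "anticoagulants", "antidepressants",
               "nsaids", "opioids", "hormone_replacement_therapy")
#: flags sharing the optional within-class correlation (latent frailty)
_CORRELATED_FLAGS = tuple(c for c in COMORBIDITIES if c != "chronic_kidney_disease") + DRUG_GROUPS

_PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_date", "diagnosis_date", "surgery_date",
    "clear_margins", "hr_positive", "stage", "t_class", "n_class", "grade",
    "her2", "side", "chemotherapy", "radiotherapy", "antibody_treatment",
    "bilateral_cancer", "prior_malignancy", "marital_status", "education",
    "employment", "death_date", "emigration_date",
]


def _days(d: date) -> int:
    return int((np.datetime64(d, "D") - _EPOCH) / np.timedelta64(1, "D"))


def _to_dates(day_numbers: np.ndarray) -> np.ndarray:
    return _EPOCH + np.asarray(np.round(day_numbers), dtype="timedelta64[D]")


@dataclass
class PopulationState:
    """Generated population with both the emitted-table view and the
    internal arrays the treatment/hazard models operate on."""

    config: ScenarioConfig
    n: int
    patient_id: np.ndarray
    latent_class: np.ndarray          # True = "aromatase-inhibitor-type" profile
    baseline_day: np.ndarray          # planned first-dispensation day number
    age: np.ndarray                   # age at baseline, years
    delay_days: np.ndarray            # diagnosis -> first dispensation
    diagnosis_day: np.ndarray
    surgery_day: np.ndarray
    flags: dict = field(default_factory=dict)    # binary covariates, int8
    cats: dict = field(default_factory=dict)     # categorical covariates, str
    clear_margins: np.ndarray | None = None
    hr_positive: np.ndarray | None = None
    bilateral: np.ndarray | None = None
    prior_malignancy: np.ndarray | None = None

    def feature(self, name: str) -> np.ndarray:
        """Resolve a named model covariate to a numeric vector."""
        if name == "age":
            return self.age
        if name == "age_c":
            return self.age - 67.0
        if name == "age_sq":
            return self.age ** 2
        if name == "log_time_from_diagnosis":
            return np.log(self.delay_days)
        if name == "log_time_from_diagnosis_sq":
            return np.log(self.delay_days) ** 2
        if ":" in name:
            cat, lev = name.split(":", 1)
            if cat not in self.cats:
                raise ConfigurationError(f"unknown categorical covariate {cat!r}")
            return (self.cats[cat] == lev).astype(float)
        if name in self.flags:
            return self.flags[name].astype(float)
        raise ConfigurationError(f"unknown model covariate {name!r}")

    def linear_predictor(self, coefs: dict) -> np.ndarray:
        eta = np.zeros(self.n)
        for name, beta in coefs.items():
            if name == "intercept":
                eta += float(beta)
            elif beta != 0.0:
                eta += float(beta) * self.feature(name)
        return eta

    def eligible_mask(self) -> np.ndarray:
        """Patients that will survive the emulation's eligibility filter
        (used to standardize the truth over the analysed population)."""
        age_at_dx = self.age - self.delay_days / 365.25
        gap = self.baseline_day - self.surgery_day
        return (
            (self.clear_margins == 1)
            & (self.hr_positive == 1)
            & np.isin(self.cats["stage"], ("1", "2", "3"))
            & (self.bilateral == 0)
            & (self.prior_malignancy == 0)
            & (age_at_dx >= 50.0)
            & (gap <= 274)
            & (gap >= 0)
        )


def _truncated_normal(rng, n, mean, sd, lo, hi):
    a, b = norm.cdf((lo - mean) / sd), norm.cdf((hi - mean) / sd)
    u = rng.random(n)
    return norm.ppf(a + u * (b - a)) * sd + mean


def generate_population(config: ScenarioConfig, seed: int | None = None) -> PopulationState:
    """Draw baseline covariates, dates and eligibility-noise flags.

    Covariates are sampled from the two-component latent-profile mixture
    described in :mod:`emutrial.calibration`. A small fraction of
    records deliberately fail individual eligibility criteria (unclear
    margins, receptor-negative, stage 4, late first dispensation,
    bilateral/prior-malignancy history) so the exclusion ledger has
    realistic work to do; these failures are independent of everything
    else, which keeps the eligible subset's covariate distribution equal
    to the profile.
    """
    config.validate()
    n = int(config.n_patients)
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed if seed is None else seed).spawn(1)[0])
    profile = config.profile

    if n == 0:
        empty = PopulationState(
            config=config, n=0, patient_id=np.empty(0, dtype=int),
            latent_class=np.empty(0, dtype=bool), baseline_day=np.empty(0),
            age=np.empty(0), delay_days=np.empty(0), diagnosis_day=np.empty(0),
            surgery_day=np.empty(0))
        for name in profile["binary"]:
            empty.flags[name] = np.empty(0, dtype=np.int8)
        empty.flags["chronic_kidney_disease"] = np.empty(0, dtype=np.int8)
        for name in profile["categorical"]:
            empty.cats[name] = np.empty(0, dtype=object)
        for attr in ("clear_margins", "hr_positive", "bilateral", "prior_malignancy"):
            setattr(empty, attr, np.empty(0, dtype=np.int8))
        return empty

    z = rng.random(n) < config.treated_share  # latent profile class

    # --- baseline year & date, restricted to the enrollment window
    start_day, end_day = _days(config.enrollment_start), _days(config.enrollment_end)
    levels, p_ai, p_tam = categorical_probs("baseline_year", profile)
    year_lo, year_hi = config.enrollment_start.year, config.enrollment_end.year
    keep = [i for i, l in enumerate(levels) if year_lo <= int(l) <= year_hi]
    if not keep:
        raise ConfigurationError("profile baseline years do not intersect window")
    levels = [levels[i] for i in keep]
    p_ai = p_ai[keep] / p_ai[keep].sum()
    p_tam = p_tam[keep] / p_tam[keep].sum()
    year_idx = _sample_categorical(rng, z, p_ai, p_tam)
    years = np.array([int(levels[i]) for i in year_idx])
    y_start = np.array([max(_days(date(y, 1, 1)), start_day) for y in years])
    y_end = np.array([min(_days(date(y, 12, 31)), end_day) for y in years])
    baseline_day = np.floor(y_start + rng.random(n) * (y_end - y_start + 1)).astype(int)

    # --- continuous covariates
    ap = profile["age"]
    age = np.where(
        z,
        _truncated_normal(rng, n, ap["aromatase_inhibitor"]["mean"],
                          ap["aromatase_inhibitor"]["sd"], ap["lo"], ap["hi"]),
        _truncated_normal(rng, n, ap["tamoxifen"]["mean"],
                          ap["tamoxifen"]["sd"], ap["lo"], ap["hi"]),
    )
    dp = profile["time_from_diagnosis"]
    log_delay = np.where(
        z,
        rng.normal(dp["aromatase_inhibitor"]["mu"], dp["aromatase_inhibitor"]["sigma"], n),
        rng.normal(dp["tamoxifen"]["mu"], dp["tamoxifen"]["sigma"], n),
    )
    delay = np.clip(np.round(np.exp(log_delay)), dp["lo"], dp["hi"])

    state = PopulationState(
        config=config, n=n, patient_id=np.arange(1, n + 1),
        latent_class=z, baseline_day=baseline_day, age=age, delay_days=delay,
        diagnosis_day=baseline_day - delay.astype(int),
        surgery_day=np.zeros(n, dtype=int))

    # --- binary flags (optionally correlated within the comorbidity/
    #     co-medication block through a shared Gaussian factor)
    rho = config.comorbidity_correlation
    shared = rng.standard_normal(n)
    for name in profile["binary"]:
        p1, p0 = binary_prevalences(name, profile)
        p = np.where(z, p1, p0)
        if name in _CORRELATED_FLAGS and rho > 0:
            u = norm.cdf(np.sqrt(rho) * shared
                         + np.sqrt(1 - rho) * rng.standard_normal(n))
        else:
            u = rng.random(n)
        state.flags[name] = (u < p).astype(np.int8)
    # chronic kidney disease: in the time-varying adjustment set but not
    # in the published baseline table; modest arm-independent prevalence
    state.flags["chronic_kidney_disease"] = (rng.random(n) < 0.02).astype(np.int8)

    # --- categorical covariates
    for name in profile["categorical"]:
        if name == "baseline_year":
            state.cats[name] = np.array([str(y) for y in years], dtype=object)
            continue
        levels_c, q_ai, q_tam = categorical_probs(name, profile)
        idx = _sample_categorical(rng, z, q_ai, q_tam)
        state.cats[name] = np.array(levels_c, dtype=object)[idx]

    # --- surgery date: between diagnosis and first fill, almost always
    #     within the 9-month rule; ~1.5% deliberately late dispensations
    late = rng.random(n) < 0.015
    hi_gap = np.minimum(273.0, delay - 1.0)
    gap = np.floor(rng.random(n) * (hi_gap - 7.0) + 7.0)
    gap_late = np.floor(rng.uniform(275, 400, n))
    gap = np.where(late, gap_late, np.maximum(gap, 1.0)).astype(int)
    state.delay_days = np.maximum(delay, gap + 30)
    state.diagnosis_day = baseline_day - state.delay_days.astype(int)
    state.surgery_day = baseline_day - gap

    # --- eligibility-noise flags
    state.clear_margins = (rng.random(n) < 0.985).astype(np.int8)
    state.hr_positive = (rng.random(n) < 0.985).astype(np.int8)
    stage4 = rng.random(n) < 0.01
    state.cats["stage"] = np.where(stage4, "4", state.cats["stage"]).astype(object)
    state.bilateral = (rng.random(n) < 0.01).astype(np.int8)
    state.prior_malignancy = (rng.random(n) < 0.01).astype(np.int8)
    return state


def _sample_categorical(rng, z, probs_ai, probs_tam):
    n = z.size
    u = rng.random(n)
    cum_ai = np.cumsum(probs_ai)
    cum_tam = np.cumsum(probs_tam)
    idx_ai = np.searchsorted(cum_ai, u, side="right")
    idx_tam = np.searchsorted(cum_tam, u, side="right")
    k = len(probs_ai) - 1
    return np.clip(np.where(z, idx_ai, idx_tam), 0, k)


# --------------------------------------------------------------------------
# treatment assignment + dispensation streams
# --------------------------------------------------------------------------

@dataclass
class DispensationResult:
    """First-fill assignment plus the simulated (potential) fill stream."""

    arm_ai: np.ndarray            # True = assigned aromatase inhibitor
    assignment_prob: np.ndarray   # P(arm = AI | covariates)
    fills: pd.DataFrame           # patient_id, drug, day, supply_days
    ai_start_day: np.ndarray      # start of aromatase-inhibitor exposure
    ai_end_day: np.ndarray        # end of aromatase-inhibitor exposure
    stop_day: np.ndarray          # day the assigned class is last taken
    switch_day: np.ndarray        # NaN when no switch


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    if eta.size == 0:
        return float(logit(np.clip(target, 1e-9, 1 - 1e-9)))
    lo, hi = -25.0, 25.0
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    return brentq(f, lo, hi, xtol=1e-12)


def generate_dispensations(state: PopulationState, config: ScenarioConfig | None = None,
                           seed: int | None = None) -> DispensationResult:
    """Assign the first-fill drug class and simulate the fill stream.

    The first-fill class follows the logistic treatment model; fills
    then repeat with jittered refill timing (mostly early, occasionally
    up to 59 days late, so adherent streams never breach the 60-day
    rule), per-interval discontinuation decisions, and stop-then-start
    switches to the other class at the next scheduled fill date.
    """
    config = config or state.config
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed if seed is None else seed).spawn(2)[1])
    n = state.n
    coefs = config.resolved_treatment_coefs()
    for drug in config.ai_drug_split:
        if drug not in AI_DRUGS:
            raise ConfigurationError(f"unknown drug code {drug!r}")

    eta = state.linear_predictor({k: v for k, v in coefs.items() if k != "intercept"})
    b0 = coefs.get("intercept")
    if b0 is None:
        b0 = _solve_intercept(eta, config.treated_share)
    p_ai = expit(b0 + eta)
    arm_ai = rng.random(n) < p_ai

    if n == 0:
        return DispensationResult(
            arm_ai=arm_ai, assignment_prob=p_ai,
            fills=pd.DataFrame(columns=["patient_id", "drug", "day", "supply_days"]),
            ai_start_day=np.empty(0), ai_end_day=np.empty(0),
            stop_day=np.empty(0), switch_day=np.empty(0))

    # per-patient monthly discontinuation hazard
    ap = config.adherence_params
    h_arm = np.where(arm_ai,
                     ap.discontinuation_hazard.get("aromatase_inhibitor", 0.0),
                     ap.discontinuation_hazard.get("tamoxifen", 0.0))
    if ap.discontinuation_coefs:
        lin = state.linear_predictor(ap.discontinuation_coefs)
        with np.errstate(divide="ignore"):
            p_stop = np.where(h_arm <= 0.0, 0.0,
                              expit(logit(np.clip(h_arm, 1e-12, 1 - 1e-12)) + lin))
        p_stop = np.where(h_arm >= 1.0, 1.0, p_stop)
    else:
        p_stop = h_arm.astype(float)

    supply_days = np.array(sorted(config.dispensation_supply_days), dtype=float)
    supply_probs = np.array([config.dispensation_supply_days[int(d)] for d in supply_days])
    supply_cum = np.cumsum(supply_probs)
    ai_levels = sorted(config.ai_drug_split)
    ai_cum = np.cumsum([config.ai_drug_split[d] for d in ai_levels])

    def draw_supply(m):
        return supply_days[np.searchsorted(supply_cum, rng.random(m), side="right").clip(0, supply_days.size - 1)]

    def draw_ai_drug(m):
        idx = np.searchsorted(ai_cum, rng.random(m), side="right").clip(0, len(ai_levels) - 1)
        return np.array(ai_levels, dtype=object)[idx]

    drug = np.where(arm_ai, draw_ai_drug(n), "tamoxifen").astype(object)
    horizon = np.minimum(
        _days(config.admin_end) - state.baseline_day,
        FOLLOWUP_MONTHS * DAYS_PER_MONTH + 90.0)

    fill_pid, fill_drug, fill_day, fill_supply = [], [], [], []

    last_fill = np.zeros(n)
    s0 = draw_supply(n)
    supply_end = s0.copy()
    active = np.ones(n, dtype=bool)
    switched = np.zeros(n, dtype=bool)
    stop_day = np.full(n, np.inf)
    switch_day = np.full(n, np.nan)
    fill_pid.append(state.patient_id.copy())
    fill_drug.append(drug.copy())
    fill_day.append(np.zeros(n))
    fill_supply.append(s0)

    max_rounds = int(FOLLOWUP_MONTHS * DAYS_PER_MONTH / supply_days.min()) + 10
    for _ in range(max_rounds):
        if not active.any():
            break
        # refill timing: mostly early, sometimes late but < 60 days
        u = rng.random(n)
        delay = np.where(u < 0.85, rng.uniform(-14.0, 0.0, n),
                         np.where(u < 0.97, rng.uniform(0.0, 30.0, n),
                                  rng.uniform(30.0, 59.0, n)))
        # refills never precede day 31, so a switch (and hence any
        # deviation) always falls after the first discrete interval
        sched = np.maximum(supply_end + delay, np.maximum(last_fill + 7.0, 31.0))
        months = np.maximum(sched - last_fill, 1.0) / DAYS_PER_MONTH
        q = 1.0 - (1.0 - p_stop) ** months
        stopping = active & ~switched & (rng.random(n) < q)
        to_switch = stopping & (rng.random(n) < ap.switch_prob)
        to_stop = stopping & ~to_switch

        stop_day[to_stop] = supply_end[to_stop]
        active[to_stop] = False
        over = active & (sched > horizon)
        active[over] = False

        if to_switch.any():
            switch_day[to_switch] = sched[to_switch]
            switched[to_switch] = True
            was_ai = to_switch & arm_ai
            was_tam = to_switch & ~arm_ai
            drug[was_ai] = "tamoxifen"
            if was_tam.any():
                drug[was_tam] = draw_ai_drug(int(was_tam.sum()))

        if active.any():
            s = draw_supply(n)
            idx = np.flatnonzero(active)
            fill_pid.append(state.patient_id[idx])
            fill_drug.append(drug[idx].copy())
            fill_day.append(sched[idx])
            fill_supply.append(s[idx])
            supply_end[idx] = np.maximum(sched[idx], supply_end[idx]) + s[idx]
            last_fill[idx] = sched[idx]

    fills = pd.DataFrame({
        "patient_id": np.concatenate(fill_pid),
        "drug": np.concatenate(fill_drug),
        "day": np.floor(np.concatenate(fill_day)),
        "supply_days": np.concatenate(fill_supply),
    }).sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    # exposure timeline of the aromatase-inhibitor class (for the hazard)
    ai_start = np.where(arm_ai, 0.0, np.where(switched, switch_day, np.inf))
    ai_end = np.where(
        arm_ai,
        np.where(switched, switch_day, np.where(np.isfinite(stop_day), stop_day, np.inf)),
        np.inf)
    return DispensationResult(arm_ai=arm_ai, assignment_prob=p_ai, fills=fills,
                              ai_start_day=ai_start, ai_end_day=ai_end,
                              stop_day=stop_day, switch_day=switch_day)


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

@dataclass
class OutcomeResult:
    death_day: np.ndarray       # NaN when no death within the horizon
    emigration_day: np.ndarray  # NaN when none

    def first_event_day(self):
        return np.fmin(self.death_day, self.emigration_day)


def generate_outcomes(state: PopulationState, dispensations: DispensationResult,
                      config: ScenarioConfig | None = None,
                      seed: int | None = None) -> OutcomeResult:
    """Simulate death interval-by-interval and independent emigration.

    The per-interval death odds are logistic in baseline covariates plus
    the treatment effect while an aromatase inhibitor is actually taken;
    tamoxifen and off-treatment intervals sit at the reference level, so
    the configured ``true_treatment_log_or`` is exactly the conditional
    aromatase-inhibitor vs tamoxifen contrast.
    """
    config = config or state.config
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed if seed is None else seed).spawn(3)[2])
    n = state.n
    if n == 0:
        return OutcomeResult(np.empty(0), np.empty(0))

    lin = state.linear_predictor(config.hazard_model_coefs)
    theta = np.full(n, config.true_treatment_log_or)
    for name, beta in config.effect_modifier_coefs.items():
        theta = theta + float(beta) * state.feature(name)

    admin_days = (_days(config.admin_end) - state.baseline_day).astype(float)

    # emigration: independent geometric clock
    if config.emigration_rate > 0:
        u = rng.random(n)
        emig_month = np.floor(np.log(u) / np.log1p(-config.emigration_rate))
        emig_day = (emig_month + rng.random(n)) * DAYS_PER_MONTH
        emig_day = np.where(emig_month < FOLLOWUP_MONTHS, emig_day, np.nan)
    else:
        rng.random(n); rng.random(n)  # keep the stream layout stable
        emig_day = np.full(n, np.nan)

    death_month = np.full(n, -1)
    alive = np.ones(n, dtype=bool)
    for k in range(FOLLOWUP_MONTHS):
        day_k = k * DAYS_PER_MONTH
        on_ai = (dispensations.ai_start_day <= day_k) & (day_k < dispensations.ai_end_day)
        p = expit(lin + theta * on_ai)
        u = rng.random(n)
        dies = alive & (u < p)
        death_month[dies] = k
        alive &= ~dies
    frac = rng.random(n)
    death_day = np.where(death_month >= 0, (death_month + frac) * DAYS_PER_MONTH, np.nan)

    # observability: death recorded if before emigration and admin end;
    # emigration recorded if before death and admin end
    death_obs = np.where(
        np.isnan(death_day) | (death_day > admin_days)
        | (~np.isnan(emig_day) & (emig_day < death_day)),
        np.nan, death_day)
    emig_obs = np.where(
        np.isnan(emig_day) | (emig_day > admin_days)
        | (~np.isnan(death_day) & (death_day <= emig_day)),
        np.nan, emig_day)
    return OutcomeResult(death_day=death_obs, emigration_day=emig_obs)


# --------------------------------------------------------------------------
# covariate history tables (diagnoses, drug co-medication fills)
# --------------------------------------------------------------------------

def _generate_history_tables(state: PopulationState, end_day: np.ndarray,
                             config: ScenarioConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diagnosis and co-medication records consistent with the baseline
    flags (onset strictly before baseline for prevalent cases; fills
    inside the 6-month lookback for prevalent users) plus post-baseline
    incidence feeding the time-varying covariates."""
    n = state.n
    rows_pid, rows_cond, rows_day = [], [], []
    for cond in COMORBIDITIES:
        flag = state.flags[cond].astype(bool)
        onset = np.where(flag, -rng.uniform(30.0, 3650.0, n), np.nan)
        new = ~flag & (rng.random(n) < 1 - (1 - config.comorbidity_onset_rate) ** FOLLOWUP_MONTHS)
        month = np.floor(rng.random(n) * FOLLOWUP_MONTHS)
        inc_day = month * DAYS_PER_MONTH + rng.random(n) * DAYS_PER_MONTH
        onset = np.where(new & (inc_day <= end_day), inc_day, onset)
        keep = ~np.isnan(onset)
        rows_pid.append(state.patient_id[keep])
        rows_cond.append(np.full(int(keep.sum()), cond, dtype=object))
        rows_day.append(onset[keep])
    diagnoses = pd.DataFrame({
        "patient_id": np.concatenate(rows_pid) if rows_pid else [],
        "condition": np.concatenate(rows_cond) if rows_cond else [],
        "day": np.floor(np.concatenate(rows_day)) if rows_day else [],
    }).sort_values(["patient_id", "condition", "day"], kind="stable").reset_index(drop=True)

    rows_pid, rows_grp, rows_day = [], [], []
    for grp in DRUG_GROUPS:
        user = state.flags[grp].astype(bool)
        # prevalent users: one fill inside the 6-month lookback
        base_fill = np.where(user, -rng.uniform(0.0, 170.0, n), np.nan)
        keep = ~np.isnan(base_fill)
        rows_pid.append(state.patient_id[keep])
        rows_grp.append(np.full(int(keep.sum()), grp, dtype=object))
        rows_day.append(base_fill[keep])
        # ongoing use: ~90-day refills with per-fill continuation 0.97
        using = user.copy()
        next_day = rng.uniform(0.0, 90.0, n)
        # non-users may initiate once during follow-up
        init = ~user & (rng.random(n) < 1 - (1 - config.drug_initiation_rate) ** FOLLOWUP_MONTHS)
        init_day = np.floor(rng.random(n) * FOLLOWUP_MONTHS) * DAYS_PER_MONTH
        for _ in range(24):
            if not using.any() and not init.any():
                break
            start_now = init & (init_day <= next_day + 1e9)  # activate initiators
            using |= start_now
            next_day = np.where(start_now, np.maximum(next_day, init_day), next_day)
            init &= ~start_now
            emit = using & (next_day <= end_day)
            if emit.any():
                rows_pid.append(state.patient_id[emit])
                rows_grp.append(np.full(int(emit.sum()), grp, dtype=object))
                rows_day.append(next_day[emit])
            cont = rng.random(n) < 0.97
            using &= cont & (next_day <= end_day)
            next_day = next_day + rng.uniform(75.0, 105.0, n)
    drug_cov = pd.DataFrame({
        "patient_id": np.concatenate(rows_pid) if rows_pid else [],
        "drug_group": np.concatenate(rows_grp) if rows_grp else [],
        "day": np.floor(np.concatenate(rows_day)) if rows_day else [],
    }).sort_values(["patient_id", "drug_group", "day"], kind="stable").reset_index(drop=True)
    return diagnoses, drug_cov


# --------------------------------------------------------------------------
# full registry assembly
# --------------------------------------------------------------------------

@dataclass
class SyntheticRegistry:
    """The four linked tables plus generator-internal ground truth."""

    config: ScenarioConfig
    patients: pd.DataFrame
    dispensations: pd.DataFrame
    diagnoses: pd.DataFrame
    drug_covariates: pd.DataFrame
    state: PopulationState
    dispensation_result: DispensationResult
    outcome_result: OutcomeResult

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"patients": self.patients, "dispensations": self.dispensations,
                "diagnoses": self.diagnoses, "drug_covariates": self.drug_covariates}


def _pills_for(drug: np.ndarray, supply: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Choose a tablet strength per fill and the pill count that delivers
    the supplied days at the defined daily dose."""
    strength = np.array([DDD_MG[d] for d in drug])
    # a fifth of tamoxifen fills use the 10 mg tablet (two per day)
    tam = np.asarray(drug) == "tamoxifen"
    half = tam & (rng.random(drug.size) < 0.2)
    strength = np.where(half, 10.0, strength)
    ddd = np.array([DDD_MG[d] for d in drug])
    pills = np.maximum(np.round(supply * ddd / strength), 1).astype(int)
    return pills, strength


def simulate_registry(config: ScenarioConfig, seed: int | None = None) -> SyntheticRegistry:
    """Generate the complete linked registry under one seed."""
    seed = config.seed if seed is None else seed
    state = generate_population(config, seed=seed)
    disp = generate_dispensations(state, config, seed=seed)
    out = generate_outcomes(state, disp, config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])

    n = state.n
    if n:
        end_day = np.where(np.isnan(out.first_event_day()),
                           (_days(config.admin_end) - state.baseline_day).astype(float),
                           out.first_event_day())
    else:
        end_day = np.empty(0)

    # truncate fills at death/emigration
    fills = disp.fills
    if len(fills):
        limit = pd.Series(end_day, index=state.patient_id)
        fills = fills[fills["day"].to_numpy()
                      <= limit.reindex(fills["patient_id"]).to_numpy()].reset_index(drop=True)
        pills, strength = _pills_for(fills["drug"].to_numpy(), fills["supply_days"].to_numpy(), rng)
        dispensations = pd.DataFrame({
            "patient_id": fills["patient_id"].astype(int),
            "drug": fills["drug"],
            "date": _to_dates(state.baseline_day[fills["patient_id"].to_numpy() - 1]
                              + fills["day"].to_numpy()),
            "pills": pills,
            "strength_mg": strength,
        })
    else:
        dispensations = pd.DataFrame(
            columns=["patient_id", "drug", "date", "pills", "strength_mg"])

    diagnoses_rel, drugcov_rel = (_generate_history_tables(state, end_day, config, rng)
                                  if n else (pd.DataFrame(columns=["patient_id", "condition", "day"]),
                                             pd.DataFrame(columns=["patient_id", "drug_group", "day"])))
    for frame, out_cols in ((diagnoses_rel, "condition"), (drugcov_rel, "drug_group")):
        if len(frame):
            frame["date"] = _to_dates(state.baseline_day[frame["patient_id"].to_numpy() - 1]
                                      + frame["day"].to_numpy())
        else:
            frame["date"] = pd.Series(dtype="datetime64[ns]")
        frame.drop(columns=["day"], inplace=True)
    diagnoses = diagnoses_rel[["patient_id", "condition", "date"]] if n else diagnoses_rel
    drug_covariates = drugcov_rel[["patient_id", "drug_group", "date"]] if n else drugcov_rel

    if n:
        birth_day = state.baseline_day - np.round(state.age * 365.25)
        death_date = np.where(np.isnan(out.death_day), np.datetime64("NaT"),
                              _to_dates(state.baseline_day + np.nan_to_num(out.death_day)))
        emig_date = np.where(np.isnan(out.emigration_day), np.datetime64("NaT"),
                             _to_dates(state.baseline_day + np.nan_to_num(out.emigration_day)))
        patients = pd.DataFrame({
            "patient_id": state.patient_id,
            "sex": "F",
            "birth_date": _to_dates(birth_day),
            "diagnosis_date": _to_dates(state.diagnosis_day),
            "surgery_date": _to_dates(state.surgery_day),
            "clear_margins": state.clear_margins,
            "hr_positive": state.hr_positive,
            "stage": state.cats["stage"],
            "t_class": state.cats["t_class"],
            "n_class": state.cats["n_class"],
            "grade": state.cats["grade"],
            "her2": state.cats["her2"],
            "side": state.cats["side"],
            "chemotherapy": state.flags["chemotherapy"],
            "radiotherapy": state.flags["radiotherapy"],
            "antibody_treatment": state.flags["antibody_treatment"],
            "bilateral_cancer": state.bilateral,
            "prior_malignancy": state.prior_malignancy,
            "marital_status": state.cats["marital_status"],
            "education": state.cats["education"],
            "employment": state.cats["employment"],
            "death_date": pd.to_datetime(death_date),
            "emigration_date": pd.to_datetime(emig_date),
        })
        # "missing" categorical levels are emitted as empty cells, the way
        # a real registry extract would look
        for col in ("grade", "her2", "education", "employment"):
            patients[col] = patients[col].replace({"missing": ""})
    else:
        patients = pd.DataFrame(columns=_PATIENT_COLUMNS)

    return SyntheticRegistry(config=config, patients=patients,
                             dispensations=dispensations, diagnoses=diagnoses,
                             drug_covariates=drug_covariates, state=state,
                             dispensation_result=disp, outcome_result=out)


# --------------------------------------------------------------------------
# counterfactual truth oracle
# --------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """True counterfactual 5-year risks under the two sustained
    strategies, standardized over the eligible population."""

    risk_ai_5y: float
    risk_tam_5y: float
    true_rd: float
    true_rr: float
    mc_se_risk_ai: float
    mc_se_risk_tam: float
    mc_se_rd: float
    n_mc: int


def true_counterfactual_risks(config: ScenarioConfig, n_mc: int = 100_000,
                              seed: int | None = None) -> SyntheticTruth:
    """Monte-Carlo counterfactual risks with no confounding and full
    adherence.

    Draws ``n_mc`` fresh patients from the configured population,
    restricts to those that would pass eligibility, and averages each
    patient's exact conditional 5-year risk 1 - (1 - p_a(L))^60 under
    both sustained strategies (sustained treatment makes the monthly
    hazard constant, so no event simulation noise enters; the only
    Monte-Carlo error is population sampling, and the reported standard
    errors shrink like 1/sqrt(n_mc)).
    """
    if int(n_mc) <= 0:
        raise ConfigurationError("n_mc must be >= 1")
    seed = config.seed if seed is None else seed
    import dataclasses as _dc
    mc_config = _dc.replace(config, n_patients=int(n_mc))
    truth_seed = int((seed * 2654435761 + 987654321) % (2**31))
    state = generate_population(mc_config, seed=truth_seed)

    lin = state.linear_predictor(config.hazard_model_coefs)
    theta = np.full(state.n, config.true_treatment_log_or)
    for name, beta in config.effect_modifier_coefs.items():
        theta = theta + float(beta) * state.feature(name)
    mask = state.eligible_mask()
    if not mask.any():
        raise ConfigurationError("no eligible patients in the truth sample")
    p_ai = expit(lin + theta)[mask]
    p_tam = expit(lin)[mask]
    r_ai = 1.0 - (1.0 - p_ai) ** FOLLOWUP_MONTHS
    r_tam = 1.0 - (1.0 - p_tam) ** FOLLOWUP_MONTHS
    m = int(mask.sum())
    rd = r_ai - r_tam
    return SyntheticTruth(
        risk_ai_5y=float(r_ai.mean()),
        risk_tam_5y=float(r_tam.mean()),
        true_rd=float(rd.mean()),
        true_rr=float(r_ai.mean() / r_tam.mean()),
        mc_se_risk_ai=float(r_ai.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan"),
        mc_se_risk_tam=float(r_tam.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan"),
        mc_se_rd=float(rd.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan"),
        n_mc=m,
    )
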