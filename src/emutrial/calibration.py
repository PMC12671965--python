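"""Published baseline profile of the emulated Swedish registry cohort.

The synthetic-registry generator is calibrated so that, in expectation,
the *eligible* cohort reproduces the arm-specific baseline covariate
distributions reported for the real 2009-2015 Swedish cohort of
aromatase-inhibitor (n = 8030) and tamoxifen (n = 4506) initiators.
The counts below are that published baseline table; they are inputs to
the generator, not outputs of it.

Calibration strategy
--------------------
Covariates are drawn from a two-component latent-profile mixture: a
latent class Z (an "aromatase-inhibitor-type" vs "tamoxifen-type"
clinical profile, mixture weight = the observed treated fraction) and,
given Z, each covariate independently from its arm-specific marginal.
The treatment actually assigned is then drawn from a logistic model on
the covariates whose default coefficients are the exact
log-likelihood-ratio (naive-Bayes dual) coefficients of that mixture,
so that P(A = 1 | X) equals the posterior P(Z = 1 | X) and the
arm-conditional covariate distributions of (X, A) match the published
profile exactly in expectation. Setting any coefficient to another
value (e.g. zero) weakens or removes that covariate's confounding.

Continuous covariates use normal (age) and log-normal (time from
diagnosis) arm-specific distributions matched to the published medians
and interquartile ranges; their log-likelihood ratios are quadratic, so
the treatment model carries linear + squared terms for each.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "COHORT_PROFILE",
    "arm_share",
    "binary_prevalences",
    "categorical_probs",
    "default_treatment_coefs",
]

# arm order everywhere: ("aromatase_inhibitor", "tamoxifen")
COHORT_PROFILE: dict = {
    "n_arm": {"aromatase_inhibitor": 8030, "tamoxifen": 4506},
    # binary flags: (count in AI arm, count in TAM arm)
    "binary": {
        "chemotherapy": (2437, 272),
        "radiotherapy": (1921, 866),
        "antibody_treatment": (677, 52),
        "cerebrovascular_disease": (205, 55),
        "diabetes": (560, 206),
        "copd": (227, 111),
        "cardiovascular_disease": (2948, 1347),
        "diabetes_drugs": (577, 217),
        "anticoagulants": (2441, 934),
        "antidepressants": (1549, 839),
        "nsaids": (3242, 1839),
        "opioids": (2552, 1223),
        "hormone_replacement_therapy": (2509, 1521),
    },
    # categoricals: level -> (count AI, count TAM); first level is the reference
    "categorical": {
        "stage": {"1": (4021, 3356), "2": (3695, 1117), "3": (314, 33)},
        "t_class": {"T1": (4422, 3421), "T2": (3080, 1006), "T3_T4": (528, 79)},
        "n_class": {"N0": (6725, 4338), "N1plus": (1305, 168)},
        "grade": {"1": (1070, 1302), "2": (4230, 2726), "3": (2338, 423),
                  "missing": (392, 55)},
        "her2": {"negative": (6734, 4101), "positive": (977, 138),
                 "missing": (319, 267)},
        "side": {"right": (3826, 2210), "left": (4204, 2296)},
        "marital_status": {"single": (997, 551), "married_cohabiting": (4739, 2673),
                           "divorced_widowed": (2294, 1282)},
        "education": {"pre_secondary": (2281, 1201), "high_school": (3282, 1854),
                      "post_secondary": (2363, 1408), "missing": (104, 43)},
        "employment": {"employed": (4411, 2611), "not_employed": (3598, 1889),
                       "missing": (21, 6)},
        "baseline_year": {"2009": (628, 611), "2010": (905, 722), "2011": (1047, 706),
                          "2012": (1047, 649), "2013": (1232, 689),
                          "2014": (1606, 574), "2015": (1565, 555)},
    },
    # age at baseline (years): normal, matched to median [IQR] 68 [62-75] / 67 [61-73]
    "age": {
        "aromatase_inhibitor": {"mean": 68.3, "sd": 9.6},
        "tamoxifen": {"mean": 67.0, "sd": 8.9},
        "lo": 45.0,
        "hi": 95.0,
    },
    # days from diagnosis to first dispensation: log-normal, matched to
    # median [IQR] 102 [61-203] / 68 [50-104]
    "time_from_diagnosis": {
        "aromatase_inhibitor": {"mu": math.log(102.0), "sigma": 0.891},
        "tamoxifen": {"mu": math.log(68.0), "sigma": 0.543},
        "lo": 21.0,
        "hi": 1500.0,
    },
}


def arm_share(profile: dict | None = None) -> float:
    """Marginal fraction assigned to the aromatase-inhibitor strategy."""
    profile = profile or COHORT_PROFILE
    n_ai = profile["n_arm"]["aromatase_inhibitor"]
    n_tam = profile["n_arm"]["tamoxifen"]
    return n_ai / (n_ai + n_tam)


def binary_prevalences(name: str, profile: dict | None = None) -> tuple[float, float]:
    """(P(flag | AI arm), P(flag | TAM arm)) for a binary covariate."""
    profile = profile or COHORT_PROFILE
    c_ai, c_tam = profile["binary"][name]
    return (c_ai / profile["n_arm"]["aromatase_inhibitor"],
            c_tam / profile["n_arm"]["tamoxifen"])


def categorical_probs(name: str, profile: dict | None = None):
    """(levels, probs_ai, probs_tam) for a categorical covariate."""
    profile = profile or COHORT_PROFILE
    table = profile["categorical"][name]
    levels = list(table.keys())
    ai = np.array([table[l][0] for l in levels], dtype=float)
    tam = np.array([table[l][1] for l in levels], dtype=float)
    return levels, ai / ai.sum(), tam / tam.sum()


def default_treatment_coefs(profile: dict | None = None) -> dict[str, float]:
    """Log-likelihood-ratio treatment-model coefficients implied by the profile.

    Binary flags get their (conditional) log odds ratio; categorical
    levels get indicator coefficients relative to the reference level;
    the continuous covariates get the linear and quadratic coefficients
    of the normal / log-normal density log-ratio. The intercept is left
    out: it is solved in-sample so the marginal treated fraction matches
    the profile (see ``synthetic_registry``).
    """
    profile = profile or COHORT_PROFILE
    coefs: dict[str, float] = {}
    for name in profile["binary"]:
        p1, p0 = binary_prevalences(name, profile)
        coefs[name] = (math.log(p1 / p0) - math.log((1 - p1) / (1 - p0)))
    for name in profile["categorical"]:
        levels, pr1, pr0 = categorical_probs(name, profile)
        ref = math.log(pr1[0] / pr0[0])
        for lev, a, b in zip(levels[1:], pr1[1:], pr0[1:]):
            coefs[f"{name}:{lev}"] = math.log(a / b) - ref
    a1, a0 = profile["age"]["aromatase_inhibitor"], profile["age"]["tamoxifen"]
    m1, s1, m0, s0 = a1["mean"], a1["sd"], a0["mean"], a0["sd"]
    coefs["age"] = m1 / s1**2 - m0 / s0**2
    coefs["age_sq"] = 0.5 * (1.0 / s0**2 - 1.0 / s1**2)
    d1 = profile["time_from_diagnosis"]["aromatase_inhibitor"]
    d0 = profile["time_from_diagnosis"]["tamoxifen"]
    m1, s1, m0, s0 = d1["mu"], d1["sigma"], d0["mu"], d0["sigma"]
    coefs["log_time_from_diagnosis"] = m1 / s1**2 - m0 / s0**2
    coefs["log_time_from_diagnosis_sq"] = 0.5 * (1.0 / s0**2 - 1.0 / s1**2)
    return coefs
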