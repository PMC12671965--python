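"""Shared fixtures: small synthetic registries and hand-built tables."""

import os

# the models here are far too small for BLAS threading to help; thread
# fan-out only adds sync overhead and run-to-run timing noise
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

from datetime import date

import numpy as np
import pandas as pd
import pytest

import emutrial as et


SCENARIO_DIR = __import__("pathlib").Path(__file__).resolve().parent.parent / "scenarios"


def load_pkg_scenario(name, **overrides):
    """Load a shipped scenario file, optionally overriding fields."""
    import dataclasses
    cfg = et.load_scenario(SCENARIO_DIR / f"{name}.yml")
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def scenario_full_followup(**overrides):
    """A scenario whose enrollment window guarantees 5 full years of
    potential follow-up for everyone (no calendar-driven censoring)."""
    defaults = dict(
        enrollment_start=date(2009, 8, 1),
        enrollment_end=date(2010, 12, 31),
        emigration_rate=0.0,
    )
    defaults.update(overrides)
    return et.ScenarioConfig(**defaults)


def full_adherence_params():
    return et.AdherenceParams(
        discontinuation_hazard={"aromatase_inhibitor": 0.0, "tamoxifen": 0.0},
        switch_prob=0.0)


@pytest.fixture(scope="session")
def small_registry():
    cfg = et.ScenarioConfig(n_patients=4000, seed=11)
    return et.simulate_registry(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_registry):
    return et.build_dataset(small_registry.tables())


def make_patient(pid, *, birth="1948-05-01", diagnosis="2011-01-01",
                 surgery="2011-02-01", clear_margins=1, hr_positive=1,
                 stage="1", t_class="T1", n_class="N0", grade="2",
                 her2="negative", side="left", chemotherapy=0, radiotherapy=0,
                 antibody_treatment=0, bilateral_cancer=0, prior_malignancy=0,
                 marital_status="married_cohabiting", education="high_school",
                 employment="employed", death_date="", emigration_date="",
                 sex="F"):
    return dict(patient_id=pid, sex=sex, birth_date=birth,
                diagnosis_date=diagnosis, surgery_date=surgery,
                clear_margins=clear_margins, hr_positive=hr_positive,
                stage=stage, t_class=t_class, n_class=n_class, grade=grade,
                her2=her2, side=side, chemotherapy=chemotherapy,
                radiotherapy=radiotherapy, antibody_treatment=antibody_treatment,
                bilateral_cancer=bilateral_cancer, prior_malignancy=prior_malignancy,
                marital_status=marital_status, education=education,
                employment=employment, death_date=death_date,
                emigration_date=emigration_date)


def make_fill(pid, drug, day, pills=100, strength=None):
    strength = strength if strength is not None else et.config.DDD_MG[drug]
    return dict(patient_id=pid, drug=drug, date=day, pills=pills,
                strength_mg=strength)


def tables_from(patients, dispensations, diagnoses=None, drug_covariates=None):
    return {
        "patients": pd.DataFrame(patients),
        "dispensations": pd.DataFrame(dispensations),
        "diagnoses": pd.DataFrame(diagnoses or [],
                                  columns=["patient_id", "condition", "date"]),
        "drug_covariates": pd.DataFrame(drug_covariates or [],
                                        columns=["patient_id", "drug_group", "date"]),
    }
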