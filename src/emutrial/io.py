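"""Reading and writing the delimited registry-style tables.

Column dictionary (all files CSV, one header row, ISO-8601 dates,
blank cell = missing):

patients.csv
    patient_id, sex, birth_date, diagnosis_date, surgery_date,
    clear_margins (0/1), hr_positive (0/1), stage (1/2/3/4),
    t_class (T1/T2/T3_T4), n_class (N0/N1plus), grade (1/2/3 or blank),
    her2 (positive/negative or blank), side (right/left),
    chemotherapy, radiotherapy, antibody_treatment, bilateral_cancer,
    prior_malignancy (each 0/1), marital_status, education, employment,
    death_date, emigration_date
dispensations.csv
    patient_id, drug (letrozole/anastrozole/exemestane/tamoxifen),
    date, pills, strength_mg
diagnoses.csv
    patient_id, condition, date
drug_covariates.csv
    patient_id, drug_group, date
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = ["TABLE_NAMES", "read_tables", "write_tables"]

TABLE_NAMES = ("patients", "dispensations", "diagnoses", "drug_covariates")

_DATE_COLUMNS = {
    "patients": ["birth_date", "diagnosis_date", "surgery_date",
                 "death_date", "emigration_date"],
    "dispensations": ["date"],
    "diagnoses": ["date"],
    "drug_covariates": ["date"],
}


def read_tables(directory) -> dict[str, pd.DataFrame]:
    """Load the four linked tables from ``<directory>/<name>.csv``."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"expected table file {path}")
        frame = pd.read_csv(path, dtype={"grade": str, "stage": str})
        for col in _DATE_COLUMNS[name]:
            if col in frame.columns:
                frame[col] = pd.to_datetime(frame[col], format="ISO8601",
                                            errors="coerce")
        tables[name] = frame
    return tables


def write_tables(tables: dict[str, pd.DataFrame], directory) -> None:
    """Write tables as CSV with ISO dates (deterministic byte output)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(directory / f"{name}.csv", index=False,
                     date_format="%Y-%m-%d", lineterminator="\n")
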