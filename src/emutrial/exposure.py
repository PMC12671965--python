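"""Continuous-treatment episodes from pharmacy dispensations.

Each fill supplies ``pills x strength / DDD`` days of drug (rounded to
whole days, at least one). Supply stockpiles: a new same-class fill
extends coverage from the later of its date and the current end of
supply. Treatment is continuous while no gap of 60 or more uncovered
days occurs and no fill of the other drug class appears; the first
breach is the patient's protocol deviation:

* gap — the 60th consecutive day without supply, i.e. 59 days after the
  last covered day (``covered_until`` marks the first uncovered day, so
  the deviation date is ``covered_until + 59``);
* switch — a fill of the other class before any gap, dated at that fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AI_CLASS, TAM_CLASS, _as_datetime
from .config import AI_DRUGS, DAYS_PER_MONTH, DDD_MG
from .errors import DataError

__all__ = ["Dispensation", "ExposureEpisode", "dispensation_duration",
           "build_episodes", "deviation_time", "episodes_for_cohort"]


@dataclass(frozen=True)
class Dispensation:
    """One pharmacy fill."""

    patient_id: int
    drug: str
    date: object          # datetime-like
    pills: int
    strength_mg: float
    ddd_mg: float | None = None

    @property
    def ddd(self) -> float:
        return DDD_MG[self.drug] if self.ddd_mg is None else self.ddd_mg


@dataclass
class ExposureEpisode:
    """The (single) continuous-exposure episode of one patient's
    assigned drug class, plus the first deviation if any."""

    patient_id: int
    drug_class: str
    start: pd.Timestamp
    covered_until: pd.Timestamp      # first uncovered day
    deviation_date: pd.Timestamp | None
    deviation_kind: str              # "gap" | "switch" | "none"


def dispensation_duration(d: Dispensation) -> int:
    """Days of supply: pills x strength / defined daily dose, rounded to
    the nearest whole day, never less than one."""
    if d.ddd <= 0:
        raise DataError(f"nonpositive defined daily dose for {d.drug!r}")
    if d.pills < 1 or d.strength_mg <= 0:
        raise DataError("dispensation must have pills >= 1 and strength > 0")
    return max(1, int(round(d.pills * d.strength_mg / d.ddd)))


def _drug_class(drug) -> str:
    return AI_CLASS if drug in AI_DRUGS else TAM_CLASS


def build_episodes(dispensations: list[Dispensation] | pd.DataFrame,
                   grace_days: int = 60,
                   followup_end=None) -> ExposureEpisode:
    """Scan one patient's date-sorted fills and locate the first
    deviation.

    ``followup_end`` (optional) closes the episode: with no further
    fills, a gap deviation is only declared when the full grace period
    elapses before follow-up ends.
    """
    if isinstance(dispensations, pd.DataFrame):
        frame = dispensations.sort_values("date", kind="stable")
        items = [
            Dispensation(int(r.patient_id), str(r.drug), pd.Timestamp(r.date),
                         int(r.pills), float(r.strength_mg),
                         float(r.ddd_mg) if "ddd_mg" in frame.columns else None)
            for r in frame.itertuples()
        ]
    else:
        items = sorted(dispensations, key=lambda d: pd.Timestamp(d.date))
    if not items:
        raise DataError("cannot build an episode from an empty fill list")

    # integer day arithmetic relative to the first fill (immune to
    # timestamp overflow for very long grace periods)
    start = pd.Timestamp(items[0].date)
    assigned = _drug_class(items[0].drug)
    covered = dispensation_duration(items[0])

    dev_day: int | None = None
    deviation_kind = "none"
    for d in items[1:]:
        when = (pd.Timestamp(d.date) - start).days
        if _drug_class(d.drug) != assigned:
            if when >= covered + grace_days:
                # the gap completed before the other-class fill
                dev_day, deviation_kind = covered + grace_days - 1, "gap"
            else:
                dev_day, deviation_kind = when, "switch"
            break
        if when >= covered + grace_days:
            dev_day, deviation_kind = covered + grace_days - 1, "gap"
            break
        covered = max(when, covered) + dispensation_duration(d)

    if deviation_kind == "none":
        # supply exhausted with no further fills: a gap deviation occurs
        # once the grace period passes, unless follow-up ends first
        candidate = covered + grace_days - 1
        end = None if followup_end is None else (pd.Timestamp(followup_end) - start).days
        if end is None or candidate < end:
            dev_day, deviation_kind = candidate, "gap"

    if dev_day is not None and dev_day <= 0:
        raise DataError("deviation on or before episode start")
    deviation_date = None if dev_day is None else start + pd.Timedelta(days=dev_day)
    return ExposureEpisode(patient_id=items[0].patient_id, drug_class=assigned,
                           start=start,
                           covered_until=start + pd.Timedelta(days=covered),
                           deviation_date=deviation_date,
                           deviation_kind=deviation_kind)


def deviation_time(episode: ExposureEpisode, baseline) -> int | None:
    """0-based discrete interval (month) containing the deviation date,
    or None while adherent. Interval k covers days
    [k x 30.4375, (k+1) x 30.4375) since baseline."""
    if episode.deviation_kind == "none" or episode.deviation_date is None:
        return None
    days = (pd.Timestamp(episode.deviation_date) - pd.Timestamp(baseline)).days
    if days <= 0:
        raise DataError("deviation date not after baseline")
    return int(days // DAYS_PER_MONTH)


def episodes_for_cohort(eligible: pd.DataFrame, dispensations: pd.DataFrame,
                        grace_days: int = 60) -> pd.DataFrame:
    """Vectorised episode construction for a whole cohort.

    Returns one row per eligible patient: drug class, coverage end,
    deviation date/kind, and the deviation's 0-based interval index
    (<NA> while adherent through follow-up).
    """
    d = dispensations.copy()
    d["date"] = _as_datetime(d["date"])
    d = d[d["patient_id"].isin(eligible["patient_id"])]
    d = d.sort_values(["patient_id", "date"], kind="stable")

    base = eligible.set_index("patient_id")
    baseline = _as_datetime(base["baseline_date"])
    fend = _as_datetime(base["followup_end_date"]) if "followup_end_date" in base \
        else pd.Series(pd.NaT, index=base.index)

    pid = d["patient_id"].to_numpy()
    day = d["date"].to_numpy("datetime64[D]").astype(np.int64)
    is_ai = d["drug"].isin(AI_DRUGS).to_numpy()
    ddd = (d["ddd_mg"].to_numpy(float) if "ddd_mg" in d.columns
           else d["drug"].map(DDD_MG).to_numpy(float))
    dur = np.maximum(1, np.round(
        d["pills"].to_numpy(float) * d["strength_mg"].to_numpy(float) / ddd)).astype(np.int64)

    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    bounds = np.r_[starts, pid.size]

    out = {k: [] for k in ("patient_id", "drug_class", "start_day", "covered_day",
                           "deviation_day", "deviation_kind")}
    for i, j in zip(bounds[:-1], bounds[1:]):
        p = pid[i]
        assigned_ai = is_ai[i]
        covered = day[i] + dur[i]
        dev_day, dev_kind = -1, "none"
        for t in range(i + 1, j):
            if is_ai[t] != assigned_ai:
                if day[t] >= covered + grace_days:
                    dev_day, dev_kind = covered + grace_days - 1, "gap"
                else:
                    dev_day, dev_kind = day[t], "switch"
                break
            if day[t] >= covered + grace_days:
                dev_day, dev_kind = covered + grace_days - 1, "gap"
                break
            covered = max(day[t], covered) + dur[t]
        out["patient_id"].append(p)
        out["drug_class"].append(AI_CLASS if assigned_ai else TAM_CLASS)
        out["start_day"].append(day[i])
        out["covered_day"].append(covered)
        out["deviation_day"].append(dev_day)
        out["deviation_kind"].append(dev_kind)

    ep = pd.DataFrame(out).set_index("patient_id")
    ep = ep.reindex(base.index)

    epoch = np.datetime64("1970-01-01", "D")
    fend_day = fend.to_numpy("datetime64[D]").astype("float64")
    open_gap = ep["deviation_kind"] == "none"
    candidate = ep["covered_day"] + grace_days - 1
    closes = open_gap & (np.isnan(fend_day) | (candidate < fend_day))
    ep.loc[closes, "deviation_day"] = candidate[closes]
    ep.loc[closes, "deviation_kind"] = "gap"

    base_day = baseline.to_numpy("datetime64[D]").astype(np.int64)
    rel = ep["deviation_day"].to_numpy(float) - base_day
    k_dev = np.floor(rel / DAYS_PER_MONTH)
    has_dev = (ep["deviation_kind"] != "none").to_numpy()
    if np.any(has_dev & (rel <= 0)):
        raise DataError("deviation on or before baseline")

    result = pd.DataFrame({
        "patient_id": ep.index,
        "drug_class": ep["drug_class"].to_numpy(),
        "start": (epoch + ep["start_day"].to_numpy("int64").astype("timedelta64[D]")),
        "covered_until": (epoch + ep["covered_day"].to_numpy("int64").astype("timedelta64[D]")),
        "deviation_date": np.where(
            has_dev, epoch + np.nan_to_num(ep["deviation_day"].to_numpy(float)).astype("int64").astype("timedelta64[D]"),
            np.datetime64("NaT")),
        "deviation_kind": ep["deviation_kind"].to_numpy(),
        "deviation_interval": pd.array(
            np.where(has_dev, k_dev, -1).astype(int), dtype="Int64"),
    })
    result.loc[~has_dev, "deviation_interval"] = pd.NA
    return result.reset_index(drop=True)
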