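"""Person-period expansion, time-varying flags, per-protocol censoring."""

import numpy as np
import pandas as pd
import pytest

import emutrial as et
from emutrial.errors import DataError
from emutrial.persontime import (attach_time_varying, censor_at_deviation,
                                 expand_person_periods)

from conftest import make_fill, make_patient, tables_from


def eligible_with(death=None, emigration=None, baseline="2011-03-01",
                  admin_end=None):
    base = pd.Timestamp(baseline)
    patients = [make_patient(
        1, death_date=death or "", emigration_date=emigration or "",
        diagnosis=str((base - pd.Timedelta(days=90)).date()),
        surgery=str((base - pd.Timedelta(days=30)).date()))]
    fills = [make_fill(1, "tamoxifen", baseline)]
    t = tables_from(patients, fills)
    kw = {"admin_end": admin_end} if admin_end else {}
    eligible, _ = et.apply_eligibility(t["patients"], t["dispensations"], **kw)
    return eligible


class TestExpansion:
    def test_death_soon_after_baseline_single_record(self):
        el = eligible_with(death="2011-03-11")   # baseline + 10 days
        pp = expand_person_periods(el)
        assert len(pp) == 1
        assert pp.iloc[0]["k"] == 0 and pp.iloc[0]["event"] == 1

    def test_alive_full_window_sixty_records(self):
        el = eligible_with(baseline="2010-03-01")
        pp = expand_person_periods(el)
        assert len(pp) == 60
        assert pp["event"].sum() == 0
        assert list(pp["k"]) == list(range(60))

    def test_administrative_censoring_three_records(self):
        # baseline 2015-10-01, administrative end 2015-12-31 -> 91 days
        el = eligible_with(baseline="2015-10-01")
        pp = expand_person_periods(el)
        assert len(pp) == 3

    def test_emigration_partial_interval_dropped(self):
        el = eligible_with(emigration="2011-03-20", baseline="2011-03-01")
        pp = expand_person_periods(el)
        assert len(pp) == 0   # emigrated inside interval 0

    def test_death_before_baseline_is_data_error(self):
        el = eligible_with(baseline="2011-03-01")
        el["followup_end_date"] = pd.Timestamp("2011-02-01")
        el["end_reason"] = "death"
        with pytest.raises(DataError):
            expand_person_periods(el)

    def test_death_assigned_to_containing_interval(self):
        el = eligible_with(death="2011-06-15", baseline="2011-03-01")  # +106 days
        pp = expand_person_periods(el)
        assert len(pp) == 4 and pp.iloc[-1]["k"] == 3   # 106 / 30.4375 -> 3
        assert pp["event"].tolist() == [0, 0, 0, 1]

    def test_total_person_time_conserved(self, small_registry):
        eligible, _ = et.apply_eligibility(small_registry.patients,
                                           small_registry.dispensations)
        pp = expand_person_periods(eligible)
        per_patient = pp.groupby("patient_id").size()
        days = (eligible["followup_end_date"]
                - eligible["baseline_date"]).dt.days.to_numpy(float)
        reason = eligible["end_reason"].to_numpy()
        expected = np.where(reason == "death", np.floor(days / 30.4375) + 1,
                            np.where(reason == "emigration",
                                     np.floor(days / 30.4375),
                                     np.ceil(days / 30.4375)))
        expected = np.clip(expected, 0, 60)
        assert per_patient.reindex(eligible["patient_id"]).fillna(0).to_numpy(
        ).sum() == expected.sum()
        # at most one event per patient, and only on the last interval
        last = pp.groupby("patient_id").tail(1).set_index("patient_id")["event"]
        by_pat = pp.groupby("patient_id")["event"].sum()
        assert (by_pat <= 1).all()
        assert (by_pat[by_pat == 1] == last[by_pat == 1]).all()


class TestTimeVarying:
    def expand(self, diagnoses=None, drugs=None):
        el = eligible_with(baseline="2010-03-01")
        pp = expand_person_periods(el)
        dg = pd.DataFrame(diagnoses or [], columns=["patient_id", "condition", "date"])
        dc = pd.DataFrame(drugs or [], columns=["patient_id", "drug_group", "date"])
        return attach_time_varying(pp, el, dg, dc)

    def test_diagnosis_in_month_seven_switches_flag_on(self):
        # month 7 starts at day 213.06; day 220 lies inside it
        pp = self.expand(diagnoses=[
            dict(patient_id=1, condition="cerebrovascular_disease",
                 date="2010-10-07")])   # baseline + 220 days
        tv = pp["tv_cerebrovascular_disease"].to_numpy()
        assert tv[:7].sum() == 0
        assert (tv[7:] == 1).all()

    def test_drug_fill_current_for_six_months(self):
        # fill in month 3 -> flag on for k in [3, 9), off after
        pp = self.expand(drugs=[
            dict(patient_id=1, drug_group="opioids", date="2010-06-10")])  # +101d
        tv = pp["tv_opioids"].to_numpy()
        assert (tv[3:9] == 1).all()
        assert tv[:3].sum() == 0 and tv[9:].sum() == 0

    def test_no_records_flags_equal_baseline(self):
        pp = self.expand()
        for cond in ("diabetes", "copd"):
            assert pp[f"tv_{cond}"].sum() == 0
        # and a pre-baseline diagnosis keeps the flag on from k = 0
        pp2 = self.expand(diagnoses=[
            dict(patient_id=1, condition="diabetes", date="2009-01-01")])
        assert (pp2["tv_diabetes"] == 1).all()


class TestCensorAtDeviation:
    def episodes(self, interval):
        return pd.DataFrame({"patient_id": [1],
                             "deviation_interval": pd.array([interval], dtype="Int64")})

    def test_deviation_at_22_keeps_22_records(self):
        el = eligible_with(baseline="2010-03-01")
        pp = expand_person_periods(el)
        kept, cf = censor_at_deviation(pp, self.episodes(22))
        assert len(kept) == 22
        assert kept["k"].max() == 21
        assert len(cf) == 23 and cf["deviates"].sum() == 1
        assert cf.loc[cf["deviates"] == 1, "k"].iloc[0] == 22

    def test_adherent_patient_identical_to_itt(self):
        el = eligible_with(baseline="2010-03-01")
        pp = expand_person_periods(el)
        kept, cf = censor_at_deviation(pp, self.episodes(pd.NA))
        assert len(kept) == len(pp)
        assert cf["deviates"].sum() == 0

    def test_deviation_beyond_followup_ignored(self):
        el = eligible_with(death="2011-06-15", baseline="2011-03-01")  # 4 records
        pp = expand_person_periods(el)
        kept, cf = censor_at_deviation(pp, self.episodes(40))
        assert len(kept) == 4 and cf["deviates"].sum() == 0

    def test_death_in_deviation_interval_wins(self):
        el = eligible_with(death="2011-06-15", baseline="2011-03-01")  # death k=3
        pp = expand_person_periods(el)
        kept, cf = censor_at_deviation(pp, self.episodes(3))
        assert kept["event"].sum() == 1          # the death is kept
        assert cf["deviates"].sum() == 0         # not censored

    def test_deviation_at_zero_is_error(self):
        el = eligible_with(baseline="2010-03-01")
        pp = expand_person_periods(el)
        with pytest.raises(DataError):
            censor_at_deviation(pp, self.episodes(0))

    def test_per_protocol_subset_of_itt(self, small_dataset):
        ds = small_dataset
        itt = pd.Series(ds.pp_row).value_counts()
        ppro = pd.Series(ds.cf_row[ds.cf_dev == 0]).value_counts()
        joined = pd.concat([itt, ppro], axis=1, keys=["itt", "pp"]).fillna(0)
        assert (joined["pp"] <= joined["itt"]).all()


class TestKaplanMeierOracle:
    def test_saturated_risk_equals_lifelines_km(self, small_registry):
        """Product-limit identity: the saturated-time pooled logistic
        standardized risk equals the Kaplan-Meier estimate."""
        from lifelines import KaplanMeierFitter

        eligible, _ = et.apply_eligibility(small_registry.patients,
                                           small_registry.dispensations)
        eligible = eligible.head(50)
        pp = expand_person_periods(eligible)
        # discrete time-to-event per patient for lifelines: interval
        # index of the last record + 1
        last = pp.groupby("patient_id").agg(t=("k", "max"), e=("event", "max"))
        k = pp["k"].to_numpy()
        y = pp["event"].to_numpy(float)
        a = np.ones(len(pp))  # single pooled "arm" (both labels identical)
        fit = et.fit_pooled_logistic(k, a, y, time_basis="saturated")
        curve = et.standardized_risk_curve(fit, 1)

        km = KaplanMeierFitter().fit(last["t"] + 1, last["e"])
        for t in range(1, int(last["t"].max()) + 2):
            ours = curve.risk_at(t)
            ref = 1.0 - float(km.predict(t))
            assert ours == pytest.approx(ref, abs=1e-10)
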