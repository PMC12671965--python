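"""Bootstrap machinery, subgroup and sensitivity runners, rendering."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import emutrial as et
from emutrial.errors import EmutrialError
from emutrial.inference import (bootstrap_cis, percentile_ci,
                                resample_frequencies, run_sensitivity,
                                run_subgroup)
from emutrial.pipeline import SUBGROUPS, estimate
from emutrial.report import (fmt_count_pct, render_effects_table,
                             render_risk_curves)

from conftest import full_adherence_params, scenario_full_followup


@pytest.fixture(scope="module")
def ds():
    cfg = scenario_full_followup(n_patients=2500, seed=42)
    reg = et.simulate_registry(cfg)
    return et.build_dataset(reg.tables())


def cfg_itt(n_bootstrap=0, **kw):
    return et.AnalysisConfig(contrast="itt", n_bootstrap=n_bootstrap, **kw)


class TestBootstrapMachinery:
    def test_percentile_ci_matches_exhaustive_enumeration(self):
        """All 27 with-replacement resamples of 3 values, enumerated
        independently, give the interval our percentile rule reports."""
        values = np.array([1.0, 4.0, 10.0])
        stats = np.array([np.mean([values[i] for i in combo])
                          for combo in itertools.product(range(3), repeat=3)])
        lo, hi = percentile_ci(stats, level=0.95)
        # hand enumeration: sorted means, linear-interpolated percentiles
        s = np.sort(stats)
        rank_lo, rank_hi = 0.025 * 26, 0.975 * 26
        exp_lo = s[0] + (s[1] - s[0]) * (rank_lo - int(rank_lo)) \
            if int(rank_lo) == 0 else None
        assert lo == pytest.approx(np.percentile(stats, 2.5))
        assert lo == pytest.approx(s[int(rank_lo)]
                                   + (s[int(rank_lo) + 1] - s[int(rank_lo)])
                                   * (rank_lo - int(rank_lo)))
        assert hi == pytest.approx(s[int(rank_hi)]
                                   + (s[int(rank_hi) + 1] - s[int(rank_hi)])
                                   * (rank_hi - int(rank_hi)))
        assert lo <= hi

    def test_resample_frequencies_sum_to_n(self):
        rng = np.random.default_rng(0)
        for n in (1, 5, 100):
            f = resample_frequencies(rng, n)
            assert f.sum() == n and f.min() >= 0

    def test_single_replicate_degenerate_ci(self, ds):
        res = bootstrap_cis(ds, cfg_itt(n_bootstrap=1, seed=5))
        lo, hi = res.ci["rd"]
        assert lo == hi == res.replicates["rd"].iloc[0]

    def test_same_seed_identical_cis(self, ds):
        r1 = bootstrap_cis(ds, cfg_itt(n_bootstrap=12, seed=9))
        r2 = bootstrap_cis(ds, cfg_itt(n_bootstrap=12, seed=9))
        assert r1.ci == r2.ci
        r3 = bootstrap_cis(ds, cfg_itt(n_bootstrap=12, seed=10))
        assert r1.ci != r3.ci

    def test_excess_failures_abort(self, ds, monkeypatch):
        calls = {"n": 0}
        real = et.pipeline.estimate

        def flaky(dataset, config, freq=None, on_nonconvergence="raise"):
            calls["n"] += 1
            if freq is not None and calls["n"] % 2 == 0:
                raise et.errors.FitError("synthetic failure")
            return real(dataset, config, freq=freq,
                        on_nonconvergence=on_nonconvergence)

        monkeypatch.setattr(et.inference, "estimate", flaky)
        with pytest.raises(EmutrialError, match="replicates failed"):
            bootstrap_cis(ds, cfg_itt(n_bootstrap=20, seed=1))


class TestSubgroups:
    def test_always_true_predicate_equals_main_analysis(self, ds, monkeypatch):
        monkeypatch.setitem(SUBGROUPS, "everyone", lambda cov: np.ones(len(cov), bool))
        main = estimate(ds, cfg_itt()).estimates
        sub = run_subgroup(ds, "everyone", cfg_itt()).estimates
        assert sub.rd == pytest.approx(main.rd, abs=1e-12)
        assert sub.rr == pytest.approx(main.rr, abs=1e-12)

    def test_complementary_predicates_partition_cohort(self, ds):
        n_lt = SUBGROUPS["age_lt_65"](ds.covariates).sum()
        n_ge = SUBGROUPS["age_ge_65"](ds.covariates).sum()
        assert n_lt + n_ge == ds.n
        users = SUBGROUPS["opioid_or_antidepressant_users"](ds.covariates).sum()
        non = SUBGROUPS["opioid_or_antidepressant_nonusers"](ds.covariates).sum()
        assert users + non == ds.n

    def test_unknown_subgroup_rejected(self, ds):
        with pytest.raises(et.errors.EmutrialError):
            run_subgroup(ds, "left_handed", cfg_itt())

    def test_effect_modification_straddles_marginal(self):
        """With a larger harmful aromatase-inhibitor effect among opioid
        users built into the generator, the user-subgroup estimate lies
        above the marginal estimate and the nonuser estimate below."""
        cfg = scenario_full_followup(
            n_patients=20000, seed=77,
            treatment_model_coefs={"intercept": 0.0},
            true_treatment_log_or=-0.1,
            effect_modifier_coefs={"opioids": 0.8},
            adherence_params=full_adherence_params())
        reg = et.simulate_registry(cfg)
        dds = et.build_dataset(reg.tables())
        marginal = estimate(dds, cfg_itt()).estimates.rd
        users = estimate(dds, cfg_itt(subgroup="opioid_or_antidepressant_users")
                         ).estimates.rd
        non = estimate(dds, cfg_itt(subgroup="opioid_or_antidepressant_nonusers")
                       ).estimates.rd
        assert non < marginal < users


class TestSensitivity:
    def test_no_missingness_complete_case_equals_main(self):
        cfg = scenario_full_followup(n_patients=2000, seed=43)
        reg = et.simulate_registry(cfg)
        # strip patients with any blank categorical, rebuild
        p = reg.patients
        complete = ~(p[["grade", "her2", "education", "employment"]]
                     .isin(["", np.nan]).any(axis=1) |
                     p[["grade", "her2", "education", "employment"]].isna().any(axis=1))
        tables = reg.tables()
        tables = {k: (v[v["patient_id"].isin(p.loc[complete, "patient_id"])]
                      if "patient_id" in v.columns else v)
                  for k, v in tables.items()}
        dds = et.build_dataset(tables)
        main = estimate(dds, cfg_itt()).estimates
        cc = estimate(dds, cfg_itt(missing_handling="complete_case")).estimates
        assert cc.rd == pytest.approx(main.rd, abs=1e-12)

    def test_no_confounding_weighting_equals_adjustment(self):
        cfg = scenario_full_followup(
            n_patients=10000, seed=44,
            treatment_model_coefs={"intercept": 0.6},
            adherence_params=full_adherence_params())
        reg = et.simulate_registry(cfg)
        dds = et.build_dataset(reg.tables())
        w = estimate(dds, cfg_itt()).estimates.rd
        g = estimate(dds, cfg_itt(adjustment="covariate_in_model")).estimates.rd
        assert abs(w - g) < 0.75    # percentage points, same data

    def test_run_sensitivity_returns_both_variants(self, ds):
        out = run_sensitivity(ds, cfg_itt(n_bootstrap=2, seed=3))
        assert set(out) == {"covariate_adjusted", "complete_case"}


class TestRendering:
    def test_rd_and_rr_cells(self):
        est = et.EffectEstimates.from_risks(0.166, 0.105, avg_hr=1.42)
        frame = render_effects_table([("users", est)])
        assert frame.loc[0, "rd_pct_points"] == "6.1"
        assert frame.loc[0, "rr"] == "1.58"
        assert frame.loc[0, "avg_hr"] == "1.42"

    def test_cells_with_cis(self):
        est = et.EffectEstimates.from_risks(0.127, 0.102, avg_hr=1.09)
        est.ci = {"rd": (0.2, 4.6), "rr": (1.02, 1.52),
                  "risk_ai_5y": (0.115, 0.138)}
        frame = render_effects_table([("itt", est)])
        assert frame.loc[0, "rd_pct_points"] == "2.5 [0.2-4.6]"
        assert frame.loc[0, "risk_ai_pct"] == "12.7 [11.5-13.8]"

    def test_empty_results_give_headers_only(self):
        frame = render_effects_table([])
        assert len(frame) == 0
        assert list(frame.columns)[0] == "analysis"
        curves = render_risk_curves({})
        assert list(curves.columns) == ["strategy", "month", "hazard",
                                        "cumulative_risk"]

    def test_count_pct_cell(self):
        assert fmt_count_pct(2437, 8030) == "2437 (30.3)"
        assert fmt_count_pct(272, 4506) == "272 (6.0)"
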