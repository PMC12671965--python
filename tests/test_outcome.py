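"""Pooled logistic hazard model, risk curves and effect measures."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

import emutrial as et
from emutrial.errors import DataError, FitError
from emutrial.outcome import (EffectEstimates, effect_measures,
                              fit_pooled_logistic, standardized_risk_curve)
from emutrial.splines import SplineSpec, rcs_basis

from conftest import full_adherence_params, scenario_full_followup


def simulate_person_periods(rng, n, hazard0, hazard1, T=60):
    """Cheap direct discrete-time simulation (no registry layer)."""
    a = (rng.random(n) < 0.5).astype(float)
    rows_k, rows_a, rows_y = [], [], []
    for i in range(n):
        h = hazard1 if a[i] else hazard0
        u = rng.random(T)
        dead = np.flatnonzero(u < h)
        stop = dead[0] if dead.size else T - 1
        ks = np.arange(stop + 1)
        rows_k.append(ks)
        rows_a.append(np.full(ks.size, a[i]))
        y = np.zeros(ks.size)
        if dead.size:
            y[-1] = 1.0
        rows_y.append(y)
    return (np.concatenate(rows_k), np.concatenate(rows_a),
            np.concatenate(rows_y))


class TestRiskCurveClosedForms:
    def saturated_with_hazard(self, hazards):
        T = len(hazards)
        k = np.tile(np.arange(T), 2)
        a = np.r_[np.zeros(T), np.ones(T)]
        y = np.tile(np.asarray(hazards, float), 2)   # fractional events
        return fit_pooled_logistic(k, a, y, time_basis="saturated")

    def test_constant_hazard_001_gives_04528(self):
        fit = self.saturated_with_hazard([0.01] * 60)
        curve = standardized_risk_curve(fit, 1)
        assert curve.risk_at(60) == pytest.approx(1 - 0.99**60, abs=1e-12)
        assert curve.risk_at(60) == pytest.approx(0.4528, abs=5e-5)

    def test_zero_hazard_zero_risk(self):
        k = np.tile(np.arange(10), 2)
        a = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.full(10, 0.2), np.zeros(10)]   # events only in arm 0
        fit = fit_pooled_logistic(k, a, y, np.ones(20), time_basis="saturated")
        curve = standardized_risk_curve(fit, 1)
        assert np.all(curve.risk == 0.0)

    def test_two_interval_product_limit(self):
        fit = self.saturated_with_hazard([0.1, 0.2])
        curve = standardized_risk_curve(fit, 0)
        assert curve.risk_at(2) == pytest.approx(0.28, abs=1e-12)

    def test_curve_is_monotone_and_starts_at_zero(self):
        fit = self.saturated_with_hazard([0.05, 0.0, 0.1, 0.02])
        curve = standardized_risk_curve(fit, 1)
        assert np.all(np.diff(np.r_[0.0, curve.risk]) >= 0)


class TestPooledLogisticFit:
    def test_weights_all_one_equals_unweighted(self):
        rng = np.random.default_rng(2)
        k, a, y = simulate_person_periods(rng, 800, 0.01, 0.015, T=24)
        f1 = fit_pooled_logistic(k, a, y, spline=SplineSpec(knots=(3, 9, 18)))
        f2 = fit_pooled_logistic(k, a, y, np.ones(k.size),
                                 spline=SplineSpec(knots=(3, 9, 18)))
        np.testing.assert_allclose(f1.fit.params, f2.fit.params, rtol=1e-10)

    def test_aggregated_fit_matches_statsmodels_rowwise(self):
        """Dual route: the cell-aggregated IRLS fit equals a statsmodels
        GLM on the raw person-period rows."""
        rng = np.random.default_rng(3)
        k, a, y = simulate_person_periods(rng, 600, 0.012, 0.02, T=30)
        spec = SplineSpec(knots=(4, 10, 20))
        ours = fit_pooled_logistic(k, a, y, spline=spec, interaction=True)
        tb = rcs_basis(k, spec)
        X = np.column_stack([np.ones(k.size), a, tb, tb * a[:, None]])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.fit.params, ref.params,
                                   rtol=1e-6, atol=1e-8)

    def test_null_effect_recovered(self):
        rng = np.random.default_rng(4)
        k, a, y = simulate_person_periods(rng, 20000, 0.01, 0.01)
        fit = fit_pooled_logistic(k, a, y, interaction=False)
        assert abs(fit.strategy_coef) < 0.1

    def test_conditional_log_or_recovered_from_generator(self):
        """Covariate-free generator with a log-OR of log(1.5) on the
        interval death odds: the unweighted pooled fit recovers it."""
        cfg = scenario_full_followup(
            n_patients=20000, seed=30,
            treatment_model_coefs={"intercept": 0.0},
            hazard_model_coefs={"intercept": float(logit(0.004))},
            true_treatment_log_or=float(np.log(1.5)),
            adherence_params=full_adherence_params())
        reg = et.simulate_registry(cfg)
        ds = et.build_dataset(reg.tables())
        fit = fit_pooled_logistic(ds.pp_k, ds.arm_ai[ds.pp_row].astype(float),
                                  ds.pp_y, interaction=False)
        assert np.exp(fit.strategy_coef) == pytest.approx(1.5, rel=0.12)

    def test_no_events_in_arm_raises(self):
        k = np.tile(np.arange(10), 2)
        a = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(9), 1.0, np.zeros(10)]
        with pytest.raises(FitError, match="no .*events"):
            fit_pooled_logistic(k, a, y)

    def test_spline_fit_approaches_saturated_with_more_events(self):
        """Mean absolute deviation between spline-smoothed and
        saturated hazards shrinks as events accumulate (constant-hazard
        data)."""
        mads = []
        for n in (500, 20000):
            rng = np.random.default_rng(60)
            k, a, y = simulate_person_periods(rng, n, 0.01, 0.01)
            spline = fit_pooled_logistic(k, a, y, interaction=False)
            spline.max_k = 60
            sat = fit_pooled_logistic(k, a, y, time_basis="saturated")
            sat.max_k = 60
            ks = np.arange(60)
            mads.append(np.mean(np.abs(spline.hazard(ks, 1) - sat.hazard(ks, 1))))
        assert mads[1] < mads[0]


class TestEffectMeasures:
    def curve(self, risks, strategy="x"):
        risks = np.asarray(risks, float)
        surv = 1 - risks
        hazard = 1 - surv / np.r_[1.0, surv[:-1]]
        return et.outcome.RiskCurve(strategy=strategy,
                                    months=np.arange(1, risks.size + 1),
                                    hazard=hazard, risk=risks)

    def flat_curve(self, final_risk):
        return self.curve(np.linspace(final_risk / 60, final_risk, 60))

    def test_rd_in_percentage_points(self):
        est = effect_measures(self.flat_curve(0.127), self.flat_curve(0.102))
        assert est.rd == pytest.approx(2.5, abs=1e-9)
        assert est.rr == pytest.approx(0.127 / 0.102, rel=1e-9)

    def test_identical_curves_null(self):
        est = effect_measures(self.flat_curve(0.08), self.flat_curve(0.08))
        assert est.rd == pytest.approx(0.0, abs=1e-12)
        assert est.rr == pytest.approx(1.0, abs=1e-12)

    def test_zero_tamoxifen_risk_warns_and_rr_absent(self):
        with pytest.warns(UserWarning, match="risk ratio undefined"):
            est = effect_measures(self.flat_curve(0.05), self.curve(np.zeros(60)))
        assert est.rr is None

    def test_short_curve_rejected(self):
        with pytest.raises(DataError):
            effect_measures(self.curve([0.01] * 30), self.curve([0.01] * 30))


def test_covariate_adjusted_standardization_matches_manual():
    """g-formula: the standardized curve equals a hand-rolled average of
    per-patient product-limit curves."""
    rng = np.random.default_rng(8)
    n = 1500
    flag = rng.integers(0, 2, n).astype(float)
    a = (rng.random(n) < 0.5).astype(float)
    rows_k, rows_a, rows_y, rows_f = [], [], [], []
    for i in range(n):
        h = 0.01 * np.exp(0.7 * flag[i]) * (1.3 if a[i] else 1.0)
        u = rng.random(24)
        dead = np.flatnonzero(u < h)
        stop = dead[0] if dead.size else 23
        ks = np.arange(stop + 1)
        rows_k.append(ks); rows_a.append(np.full(ks.size, a[i]))
        y = np.zeros(ks.size); y[-1] = 1.0 if dead.size else 0.0
        rows_y.append(y); rows_f.append(np.full(ks.size, flag[i]))
    k = np.concatenate(rows_k); av = np.concatenate(rows_a)
    y = np.concatenate(rows_y); f = np.concatenate(rows_f).reshape(-1, 1)
    spec = SplineSpec(knots=(4, 10, 20))
    fit = fit_pooled_logistic(k, av, y, spline=spec, X_cov=f,
                              covariate_names=("flag",))
    X_pop = flag.reshape(-1, 1)
    curve = standardized_risk_curve(fit, 1, X_pop=X_pop)
    # manual: average product-limit over patients
    ks = np.arange(fit.max_k)
    risks = []
    for v in (0.0, 1.0):
        h = fit.fit.predict_proba(fit.design(ks, np.ones(ks.size),
                                             np.full((ks.size, 1), v)))
        risks.append(1 - np.cumprod(1 - h))
    w1 = flag.mean()
    expected = w1 * risks[1] + (1 - w1) * risks[0]
    np.testing.assert_allclose(curve.risk, expected, rtol=1e-10)
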