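"""Kaplan-Meier, log-rank, Cox PH (Efron) and Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cmslike import (
    CohortConfig,
    SurvivalParams,
    cox_fit,
    derive_endpoints,
    enter_method_pipeline,
    generate_cohort,
    km_estimate,
    logrank_test,
    schoenfeld_check,
    survival_at,
)


class TestEndpoints:
    def test_cause_of_death_handling(self):
        df = pd.DataFrame(
            {
                "os_time": [2.0, 3.0, 5.0],
                "os_event": [True, True, False],   # CRC death, other death, alive
                "dss_event": [True, False, False],
            }
        )
        (t, os_e), (dt, dss_e) = derive_endpoints(df)
        assert os_e.tolist() == [True, True, False]
        assert dss_e.tolist() == [True, False, False]
        assert np.array_equal(t, dt)

    def test_negative_time_rejected(self):
        df = pd.DataFrame({"os_time": [-1.0], "os_event": [True],
                           "dss_event": [True]})
        with pytest.raises(ValueError):
            derive_endpoints(df)

    def test_dss_must_be_subset(self):
        df = pd.DataFrame({"os_time": [1.0], "os_event": [False],
                           "dss_event": [True]})
        with pytest.raises(ValueError):
            derive_endpoints(df)


class TestKaplanMeier:
    def test_hand_product_limit_oracle(self):
        # {(1,e),(2,e),(3,c),(4,e)}: S(1)=3/4, S(2)=1/2, S(4)=0
        curve = km_estimate([1, 2, 3, 4], [True, True, False, True])
        assert curve.survival == pytest.approx([0.75, 0.5, 0.0])
        s, lo, hi = survival_at(curve, 2.5)
        assert s == 0.5 and lo <= s <= hi

    def test_no_events_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [False, False, False])
        assert curve.times.size == 0
        assert survival_at(curve, 10.0) == (1.0, 1.0, 1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5.0, 200)
        curve = km_estimate(t, np.ones(200, bool))
        for q in (1.0, 3.0, 7.0):
            emp = np.mean(t > q)
            assert survival_at(curve, q)[0] == pytest.approx(emp, abs=1e-12)

    def test_monotone_and_ci_contains_estimate(self, rng):
        t = rng.exponential(5.0, 300)
        e = rng.random(300) < 0.7
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all(curve.ci_low <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_high + 1e-12)

    def test_all_zero_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 0.0], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self, rng):
        t = rng.exponential(5.0, 100)
        e = rng.random(100) < 0.8
        chi2, df, p = logrank_test([t, t.copy()], [e, e.copy()])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = [rng.exponential(s, 80) for s in (4.0, 6.0, 5.0)]
        e = [rng.random(80) < 0.8 for _ in range(3)]
        chi2, df, p = logrank_test(t, e)
        res = multivariate_logrank_test(
            np.concatenate(t),
            np.repeat([0, 1, 2], 80),
            np.concatenate(e),
        )
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-6)
        assert p == pytest.approx(res.p_value, rel=1e-6)

    def test_two_sample_agrees_with_permutation_oracle(self, rng):
        t = np.concatenate([rng.exponential(3.0, 20), rng.exponential(6.0, 20)])
        e = np.ones(40, bool)
        grp = np.repeat([0, 1], 20)
        chi2_obs, _, p_asym = logrank_test([t[grp == 0], t[grp == 1]],
                                           [e[grp == 0], e[grp == 1]])
        perm_stats = []
        for _ in range(2000):
            g = rng.permutation(grp)
            c, _, _ = logrank_test([t[g == 0], t[g == 1]],
                                   [e[g == 0], e[g == 1]])
            perm_stats.append(c)
        p_perm = np.mean(np.asarray(perm_stats) >= chi2_obs - 1e-12)
        se = np.sqrt(p_perm * (1 - p_perm) / 2000)
        assert abs(p_asym - p_perm) <= max(4 * se, 0.02)

    def test_no_events_undefined(self):
        chi2, df, p = logrank_test([[1.0, 2.0], [3.0]],
                                   [[False, False], [False]])
        assert np.isnan(chi2) and np.isnan(p)


def _naive_partial_loglik(beta, x, t, e):
    """Direct O(n^2) partial log likelihood (no ties in the data used)."""
    ll = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_matches_brute_force_grid_oracle(self, rng):
        x = rng.integers(0, 2, 18).astype(float)
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        e = rng.random(18) < 0.85
        e[0] = True
        fit = cox_fit(x[:, None], t, e)
        res = minimize_scalar(lambda b: -_naive_partial_loglik(b, x, t, e),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = np.ceil(rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2)) * 4) / 4
        e = rng.random(n) < 0.75
        fit = cox_fit(np.column_stack([x1, x2]), t, e, names=["x1", "x2"])
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")  # Efron ties by default
        assert fit.coef == pytest.approx(cph.params_.values, abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_.values, abs=1e-6)
        assert fit.p == pytest.approx(
            cph.summary["p"].values, rel=1e-4
        )

    def test_generator_parameter_recovery(self):
        params = SurvivalParams(log_hrs=(0.5, 0.0, 0.0, 0.0),
                                censoring_rate=0.0, horizon=1e9)
        cfg = CohortConfig(n_patients=4000,
                           subtype_prevalence=(0.5, 0.5, 0.0, 0.0),
                           survival_params=params, seed=31)
        patients, _, _ = generate_cohort(cfg)
        x = (patients["latent_subtype"] == "CMS1L").to_numpy(float)
        fit = cox_fit(x[:, None],
                      patients["os_time"].to_numpy(),
                      patients["os_event"].to_numpy(bool))
        assert fit.coef[0] == pytest.approx(0.5, abs=0.15)

    def test_constant_covariate_rejected(self, rng):
        t = rng.exponential(1.0, 20)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones((20, 1)), t, np.ones(20, bool))

    def test_fewer_events_than_covariates_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.eye(3), [1.0, 2.0, 3.0], [False, False, False])

    def test_separation_warns(self):
        # the covariate perfectly orders the event times
        t = np.arange(1.0, 11.0)
        x = (t > 5).astype(float)
        with pytest.warns(RuntimeWarning, match="separation"):
            cox_fit(x[:, None], t, np.ones(10, bool))


class TestEnterMethod:
    @staticmethod
    def _simulate(n, rng, age_hr=0.0, stage_hr=0.0, subtype_hr=0.0):
        age = rng.integers(0, 2, n).astype(float)
        stage = rng.choice(["I", "II", "III"], n)
        subtype = rng.choice(["CMS2-like", "CMS1-like"], n)
        lp = (age_hr * age
              + stage_hr * (stage == "III")
              + subtype_hr * (subtype == "CMS1-like"))
        t = rng.exponential(1.0 / (0.1 * np.exp(lp)))
        cens = rng.exponential(30.0, n)
        return pd.DataFrame(
            {
                "age_high": age,
                "stage": stage,
                "cms": subtype,
                "os_time": np.minimum(t, cens),
                "os_event": t <= cens,
            }
        )

    def test_null_candidates_usually_skip_multivariable(self):
        skipped = 0
        for seed in range(10):
            df = self._simulate(150, np.random.default_rng(seed))
            out = enter_method_pipeline(df, ["age_high", "stage", "cms"])
            if out["multivariable"] is None:
                assert out["selected"] == []
                skipped += 1
        assert skipped >= 6  # ~0.95**4 per run: the step is usually skipped

    def test_true_effects_all_selected_and_jointly_fit(self, rng):
        df = self._simulate(1500, rng, age_hr=0.7, stage_hr=0.8, subtype_hr=0.6)
        out = enter_method_pipeline(
            df, ["age_high", "stage", "cms"],
            references={"cms": "CMS2-like", "stage": "I"},
        )
        assert set(out["selected"]) == {"age_high", "stage", "cms"}
        multi = out["multivariable"]
        # one row per non-reference level per selected variable
        assert len(multi.names) == 1 + 2 + 1
        assert multi.converged

    def test_reference_level_excluded_from_design(self, rng):
        df = self._simulate(800, rng, subtype_hr=0.9)
        out = enter_method_pipeline(df, ["cms"], references={"cms": "CMS2-like"})
        uni = out["univariable"]["cms"]
        assert uni.names == ["cms[CMS1-like]"]
        assert uni.hr[0] > 1.0


class TestSchoenfeld:
    def test_residuals_exist_only_at_event_times(self, rng):
        n = 120
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.6
        fit = cox_fit(x, t, e)
        out = schoenfeld_check(fit, x, t, e)
        assert out.attrs["residuals"].shape == (e.sum(), 1)
        assert np.isin(out.attrs["event_times"], t[e]).all()

    def test_too_few_events_rejected(self, rng):
        x = rng.normal(size=(10, 1))
        t = rng.exponential(1.0, 10)
        e = np.zeros(10, bool)
        e[0] = True
        fit_e = np.zeros(10, bool)
        fit_e[:2] = True
        fit = cox_fit(x, t, fit_e)
        with pytest.raises(ValueError):
            schoenfeld_check(fit, x, t, e)

    def test_detects_strongly_time_varying_effect(self):
        """An effect that reverses sign at the median event time should be
        flagged by the correlation test in most runs."""
        detections = 0
        n = 300
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.integers(0, 2, n).astype(float)
            # piecewise hazard: strong positive effect before tau, strong
            # negative after
            tau = 1.0
            base, hi = 0.5, np.exp(1.5)
            rate1 = base * np.where(x == 1, hi, 1.0)
            rate2 = base * np.where(x == 1, 1.0 / hi, 1.0)
            u = r.random(n)
            t1 = -np.log(u) / rate1
            t = np.where(t1 < tau, t1, tau + (t1 - tau) * rate1 / rate2)
            e = np.ones(n, bool)
            fit = cox_fit(x[:, None], t, e)
            out = schoenfeld_check(fit, x[:, None], t, e)
            if out["p"].iloc[0] <= 0.05:
                detections += 1
        assert detections >= 80
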