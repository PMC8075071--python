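import math
import warnings

import numpy as np
import pandas as pd
import pytest

import copdwatch as cw
from copdwatch.analysis import FitError, PeriodRow, period_table_frame
from copdwatch.cohort import ExacerbationEvent, PatientProfile
from oracles import poisson_irls


def _profile(pid, followup=500, gold="D", sex="male", age=67.0, ics=True):
    return PatientProfile(
        patient_id=pid, age=age, sex=sex, gold=gold, ics_use=ics, fev1pp=45.0,
        latent_pre_rate=2.4, latent_hosp_days_rate=8.0,
        followup_post=followup, died=False,
    )


def _row(pid, intervention, exposure, n_exac, n_hosp=0, **kw):
    defaults = dict(age=67.0, sex="male", gold="D", ics_use=True)
    defaults.update(kw)
    return PeriodRow(
        patient_id=pid, intervention=intervention, exposure_days=float(exposure),
        n_exacerbations=n_exac, n_hosp_days=n_hosp, **defaults,
    )


def _paired_rows(pre_counts, post_counts, post_exposures=None, **kw):
    post_exposures = post_exposures or [365] * len(pre_counts)
    rows = []
    for i, (a, b, e) in enumerate(zip(pre_counts, post_counts, post_exposures), 1):
        # vary covariates so adjusted designs stay full rank
        covars = dict(age=60.0 + i, sex="female" if i % 2 else "male",
                      ics_use=bool(i % 3), **kw)
        rows.append(_row(i, 0, 365, a, a, **covars))
        rows.append(_row(i, 1, e, b, b, **covars))
    return rows


class TestBuildPeriodTable:
    def test_counts_and_exposures(self):
        p = _profile(1, followup=420)
        pre = {1: [ExacerbationEvent(10, "severe", 4),
                   ExacerbationEvent(100, "severe", 3),
                   ExacerbationEvent(300, "severe", 3)]}
        post = {1: []}
        rows = cw.build_period_table([p], pre, post)
        pre_row, post_row = rows
        assert pre_row.n_exacerbations == 3 and pre_row.n_hosp_days == 10
        assert pre_row.exposure_days == 365  # fixed regardless of events
        assert post_row.n_exacerbations == 0 and post_row.n_hosp_days == 0
        assert post_row.exposure_days == 420

    def test_missing_period_rejected(self):
        p = _profile(1)
        with pytest.raises(KeyError, match="post"):
            cw.build_period_table([p], {1: []}, {})

    def test_missing_gold_becomes_none(self):
        p = _profile(1, gold="missing")
        rows = cw.build_period_table([p], {1: []}, {1: []})
        assert rows[0].gold is None


class TestFitIrr:
    def test_symmetric_table_gives_unit_irr(self):
        rows = _paired_rows([2, 3, 1, 4], [2, 3, 1, 4])
        fit = cw.fit_irr(rows, "exacerbations", 1)
        assert fit.irr == pytest.approx(1.0, abs=1e-8)

    def test_intervention_only_equals_pooled_rate_ratio(self):
        """With only intercept and indicator, the Poisson estimate is the
        ratio of pooled post rate to pooled pre rate."""
        rows = _paired_rows([2, 3, 1], [1, 0, 1], post_exposures=[400, 500, 600])
        fit = cw.fit_irr(rows, "exacerbations", 1, working_correlation="independence")
        expected = (2 / 1500) / (6 / 1095)
        assert fit.irr == pytest.approx(expected, abs=1e-9)
        assert fit.irr == pytest.approx(0.2433, abs=5e-4)

    def test_ci_invariants(self, medium_table):
        fit = cw.fit_irr(medium_table, "exacerbations", 2)
        assert fit.ci_low <= fit.irr <= fit.ci_high
        assert fit.irr == pytest.approx(math.exp(fit.coef))
        assert fit.ci_low == pytest.approx(
            math.exp(fit.coef - 1.959963984540054 * fit.robust_se)
        )

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_independence_gee_matches_irls_oracle(self, medium_table, model_id):
        """GEE point estimates with independence working correlation equal a
        hand-coded Poisson IRLS fit to 1e-6."""
        fit = cw.fit_irr(medium_table, "exacerbations", model_id,
                         working_correlation="independence")
        df = period_table_frame(medium_table)
        if model_id >= 3:
            df = df[df["gold"].notna()]
        cols = [np.ones(len(df)), df["intervention"].to_numpy(float)]
        if model_id >= 2:
            cols.append((df["sex"] == "female").to_numpy(float))
            cols.append(df["age"].to_numpy(float))
        if model_id >= 3:
            for g in sorted(df["gold"].dropna().unique())[1:]:
                cols.append((df["gold"] == g).to_numpy(float))
        if model_id >= 4:
            cols.append(df["ics_use"].to_numpy(float))
        X = np.column_stack(cols)
        beta = poisson_irls(X, df["n_exacerbations"], np.log(df["exposure_days"]))
        assert fit.coef == pytest.approx(beta[1], abs=1e-6)

    def test_models_drop_missing_gold(self):
        rows = _paired_rows([2, 1, 3, 2, 4, 1, 2, 3], [1, 0, 1, 1, 2, 0, 1, 1])
        rows = [
            PeriodRow(**{**r.__dict__, "gold": None}) if r.patient_id == 1 else r
            for r in rows
        ]
        fit2 = cw.fit_irr(rows, "exacerbations", 2)
        fit3 = cw.fit_irr(rows, "exacerbations", 3)
        assert fit2.n_patients == 8
        assert fit3.n_patients == 7

    def test_offset_scaling_invariance(self):
        """Scaling post exposures and counts by the same factor leaves the
        pooled-rate IRR unchanged."""
        rows = _paired_rows([2, 3, 1], [1, 0, 1], post_exposures=[400, 500, 600])
        scaled = [
            PeriodRow(**{**r.__dict__,
                         "exposure_days": r.exposure_days * 3,
                         "n_exacerbations": r.n_exacerbations * 3})
            if r.intervention == 1 else r
            for r in rows
        ]
        f1 = cw.fit_irr(rows, "exacerbations", 1, working_correlation="independence")
        f2 = cw.fit_irr(scaled, "exacerbations", 1, working_correlation="independence")
        assert f2.irr == pytest.approx(f1.irr, abs=1e-9)

    def test_adjustment_nearly_inert_in_prepost_design(self, medium_table):
        """Within-patient pre/post contrasts make covariate adjustment nearly
        inert: model 1 and model 2 IRRs agree closely."""
        f1 = cw.fit_irr(medium_table, "exacerbations", 1)
        f2 = cw.fit_irr(medium_table, "exacerbations", 2)
        assert f2.irr == pytest.approx(f1.irr, rel=0.02)

    def test_too_few_clusters(self):
        rows = _paired_rows([2], [1])
        with pytest.raises(FitError, match="clusters"):
            cw.fit_irr(rows, "exacerbations", 1)

    def test_unbalanced_table_rejected(self):
        rows = [_row(1, 0, 365, 2), _row(1, 0, 365, 3), _row(2, 0, 365, 1),
                _row(2, 1, 400, 1)]
        with pytest.raises(ValueError, match="pre and one post"):
            cw.fit_irr(rows, "exacerbations", 1)

    def test_parameter_recovery_light(self):
        """Mean estimate over a few simulated cohorts sits near the
        generative log rate ratio."""
        est = []
        for seed in range(8):
            cfg = cw.SimConfig(n_patients=400, seed=100 + seed)
            profiles, pre, post, _ = cw.simulate_cohort_tables(cfg, daily=False)
            fit = cw.fit_irr(cw.build_period_table(profiles, pre, post),
                             "exacerbations", 1)
            est.append(fit.coef)
        assert np.mean(est) == pytest.approx(math.log(0.310), abs=0.05)


class TestSelectFamily:
    @staticmethod
    def _counts_table(counts_pre, counts_post):
        return _paired_rows(list(counts_pre), list(counts_post))

    def test_poisson_counts_select_poisson(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = self._counts_table(rng.poisson(2.0, 300), rng.poisson(2.0, 300))
            hits += cw.select_family(table, "exacerbations") == "poisson"
        assert hits >= 19

    def test_nb_counts_select_negative_binomial(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lam = rng.gamma(0.5, 2.0 / 0.5, size=300)  # mean 2, size 0.5
            lam2 = rng.gamma(0.5, 2.0 / 0.5, size=300)
            table = self._counts_table(rng.poisson(lam), rng.poisson(lam2))
            hits += cw.select_family(table, "exacerbations") == "negative_binomial"
        assert hits >= 19

    def test_default_cohort_is_poisson(self, medium_table):
        assert cw.select_family(medium_table, "exacerbations") == "poisson"
        assert cw.select_family(medium_table, "hosp_days") == "negative_binomial"

    def test_all_zero_outcome_rejected(self):
        rows = _paired_rows([0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError, match="zero"):
            cw.select_family(rows, "exacerbations")


class TestCcqTrend:
    @staticmethod
    def _long(n_patients, slope_per_day, rng, noise=0.3, n_obs=8):
        rows = []
        for pid in range(1, n_patients + 1):
            base = rng.normal(3.0, 1.0)
            for k in range(n_obs):
                day = k * 7
                rows.append((pid, day, base + slope_per_day * day + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["patient_id", "day", "ccq"])

    def test_increasing_scores_positive_slope(self, rng):
        df = self._long(20, 0.01, rng, noise=0.01)
        slope, p = cw.ccq_trend(df)
        assert slope > 0
        assert p < 0.01

    def test_time_reversal_negates_slope(self, rng):
        df = self._long(15, 0.005, rng)
        slope, _ = cw.ccq_trend(df)
        rev = df.copy()
        rev["day"] = rev["day"].max() - rev["day"]
        slope_rev, _ = cw.ccq_trend(rev)
        assert slope_rev == pytest.approx(-slope, rel=1e-6)

    def test_constant_scores_warn_degenerate(self):
        df = pd.DataFrame(
            {"patient_id": [1, 1, 2, 2], "day": [0, 7, 0, 7], "ccq": [3.0] * 4}
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            slope, p = cw.ccq_trend(df)
        assert slope == 0.0 and math.isnan(p)

    def test_null_type_one_error(self, rng):
        """Under no trend the robust test rejects at ~5% (sandwich tests are
        slightly anti-conservative, so many clusters are needed for this to
        sit near nominal)."""
        rejections = 0
        n_sims = 400
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_sims):
                df = self._long(200, 0.0, rng, noise=0.5, n_obs=5)
                _, p = cw.ccq_trend(df)
                rejections += p < 0.05
        assert abs(rejections / n_sims - 0.05) < 0.025
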