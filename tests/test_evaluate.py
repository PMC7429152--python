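"""Cohort-level evaluation: OR per SD, decile risk, AUC, Youden cutoffs,
clinical risk score baseline, exacerbation models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from copdprs.evaluate import (
    SeparationError,
    assign_deciles,
    auc_models,
    clinical_risk_score,
    decile_analysis,
    exacerbation_models,
    fit_or_per_sd,
    youden_and_metrics,
)
from copdprs.roc import mann_whitney_auc, delong_variance


def _cohort(n=2000, seed=0, effect=0.8):
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    age = rng.normal(60, 8, n)
    sex = rng.integers(0, 2, n)
    py = rng.gamma(2, 12, n)
    lin = -1.5 + effect * s + 0.02 * (age - 60)
    y = rng.binomial(1, 1 / (1 + np.exp(-lin)))
    ph = pd.DataFrame({
        "copd": y.astype(float), "age": age, "sex": sex, "height": rng.normal(170, 8, n),
        "pack_years": py,
    })
    return ph, s


class TestOrPerSd:
    def test_binary_exposure_matches_2x2_odds_ratio(self):
        ph, s = _cohort(n=3000, seed=1)
        x = (s > 0).astype(float)
        res = fit_or_per_sd(ph, x, covariates=())
        y = ph["copd"].to_numpy()
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        assert res.estimate == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_irrelevant_covariate_barely_moves_estimate(self):
        ph, s = _cohort(n=4000, seed=2)
        rng = np.random.default_rng(3)
        ph["noise"] = rng.standard_normal(len(ph))
        base = fit_or_per_sd(ph, s, covariates=())
        adj = fit_or_per_sd(ph, s, covariates=("noise",))
        assert abs(adj.estimate - base.estimate) < 0.5 * base.se

    def test_affine_rescaling_invariance_after_standardization(self):
        ph, s = _cohort(n=2000, seed=4)
        std = (s - s.mean()) / s.std()
        rescaled = 5.0 * s + 3.0
        std2 = (rescaled - rescaled.mean()) / rescaled.std()
        r1 = fit_or_per_sd(ph, std, covariates=("age", "sex"))
        r2 = fit_or_per_sd(ph, std2, covariates=("age", "sex"))
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-10)

    def test_separation_detected(self):
        ph = pd.DataFrame({"copd": [0.0] * 20 + [1.0] * 20})
        s = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            fit_or_per_sd(ph, s, covariates=())

    def test_single_class_rejected(self):
        ph = pd.DataFrame({"copd": np.zeros(50)})
        with pytest.raises(ValueError):
            fit_or_per_sd(ph, np.random.default_rng(0).standard_normal(50), covariates=())


class TestDeciles:
    def test_constant_score_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            assign_deciles(np.ones(100))

    def test_hand_counts_fixture(self):
        # decile10: 30 cases/70 controls; decile1: 10 cases/90 controls
        scores = np.arange(1000, dtype=float)
        labels = np.zeros(1000)
        labels[:10] = 1            # decile 1 cases
        labels[900:930] = 1        # decile 10 cases
        res = decile_analysis(scores, labels, reference="decile1")
        top = res[-1]
        assert top.model == "decile10 vs decile1"
        assert top.odds_ratio == pytest.approx((30 * 90) / (70 * 10), abs=1e-9)

    def test_decile_or_matches_covariate_free_logistic(self):
        ph, s = _cohort(n=3000, seed=5)
        res = decile_analysis(s, ph["copd"].to_numpy())
        dec = assign_deciles(s)
        m = (dec == 10) | (dec == 1)
        y = ph["copd"].to_numpy()[m]
        x = (dec[m] == 10).astype(float)
        import statsmodels.api as sm
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert res[-1].estimate == pytest.approx(fit.params[1], abs=1e-6)

    def test_monotone_risk_gradient_under_generating_model(self):
        from scipy.stats import spearmanr
        ph, s = _cohort(n=20000, seed=6, effect=0.8)
        res = decile_analysis(s, ph["copd"].to_numpy())
        ors = [r.odds_ratio for r in res]
        assert spearmanr(ors, np.arange(len(ors))).statistic > 0.8

    def test_middle_tertile_reference(self):
        ph, s = _cohort(n=3000, seed=7)
        res = decile_analysis(s, ph["copd"].to_numpy(), reference="middle_tertile")
        assert len(res) == 10
        assert res[9].model == "decile10 vs middle_tertile"

    def test_zero_cell_flagged(self):
        scores = np.arange(100, dtype=float)
        labels = np.zeros(100)
        labels[95:] = 1  # all decile-10; decile 1 has zero cases
        res = decile_analysis(scores, labels)
        assert "zero-cell continuity correction" in res[-1].flags


class TestAuc:
    def test_perfect_separation_auc_one(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        s = np.r_[np.zeros(10), np.ones(10) + 1]
        assert mann_whitney_auc(y, s) == 1.0

    def test_four_point_fixture(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([2.0, 3.0, 1.0, 2.5])
        assert mann_whitney_auc(y, s) == pytest.approx(0.75)

    def test_equals_concordant_pair_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(10, 51)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 6, n).astype(float)  # many ties
            conc = 0.0
            for i, j in itertools.product(np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]):
                conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            expected = conc / (y.sum() * (n - y.sum()))
            assert mann_whitney_auc(y, s) == pytest.approx(expected, abs=1e-12)

    def test_model_comparison_prefers_added_signal(self):
        ph, s = _cohort(n=4000, seed=9)
        res = auc_models(ph, s)
        by_name = {r.model: r for r in res}
        assert by_name["clinical+prs"].auc > by_name["clinical"].auc
        other, delta, p = by_name["clinical+prs"].comparison
        assert other == "clinical" and delta > 0 and p < 0.01

    def test_roc_curve_monotone(self):
        ph, s = _cohort(n=500, seed=10)
        res = auc_models(ph, s)
        sens = [pt[0] for pt in res[0].curve]
        spec = [pt[1] for pt in res[0].curve]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))


class TestYouden:
    def test_perfect_score(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        s = np.r_[np.zeros(5), np.ones(5)]
        m = youden_and_metrics(y, s)
        assert m.youden == pytest.approx(1.0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_matches_exhaustive_threshold_sweep(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([2.0, 3.0, 1.0, 2.5])
        m = youden_and_metrics(y, s)
        best_j = -np.inf
        for t in [np.inf] + sorted(set(s), reverse=True):
            pred = s >= t
            sens = (pred & (y == 1)).sum() / 2
            spec = (~pred & (y == 0)).sum() / 2
            best_j = max(best_j, sens + spec - 1)
        assert m.youden == pytest.approx(best_j)
        assert 2.5 < m.cutoff <= 3.0
        assert m.ppv == 1.0  # only cases above the cutoff

    def test_ppv_npv_follow_bayes(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 400).astype(float)
        s = y + rng.standard_normal(400)
        m = youden_and_metrics(y, s)
        prev = y.mean()
        ppv_bayes = (m.sensitivity * prev) / (m.sensitivity * prev + (1 - m.specificity) * (1 - prev))
        assert m.ppv == pytest.approx(ppv_bayes, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            youden_and_metrics(np.ones(10), np.arange(10.0))


class TestClinicalRiskScore:
    def test_null_coefficient_recovery(self):
        rng = np.random.default_rng(12)
        n = 6000
        age = rng.normal(60, 8, n)
        ph = pd.DataFrame({
            "age": age, "sex": rng.integers(0, 2, n), "pack_years": rng.gamma(2, 12, n),
            "copd": rng.binomial(1, 1 / (1 + np.exp(-(-2 + 0.08 * (age - 60))))).astype(float),
        })
        params, _ = clinical_risk_score(ph, ph)
        import statsmodels.api as sm
        X = sm.add_constant(ph[["age", "sex", "pack_years"]].to_numpy())
        se = sm.Logit(ph["copd"], X).fit(disp=0).bse[3]
        assert abs(params["pack_years"]) < 2 * se

    def test_in_sample_auc_consistency(self):
        ph, s = _cohort(n=2000, seed=13)
        params, prof = clinical_risk_score(ph, ph)
        auc_lin = mann_whitney_auc(ph["copd"], prof.std)
        res = auc_models(ph, s)
        clinical = [r for r in res if r.model == "clinical"][0]
        assert auc_lin == pytest.approx(clinical.auc, abs=1e-10)  # monotone transform

    def test_external_application_does_not_refit(self):
        ph, _ = _cohort(n=1000, seed=14)
        other, _ = _cohort(n=1000, seed=15)
        params, _ = clinical_risk_score(ph, other)
        params2, _ = clinical_risk_score(ph, ph)
        assert params == params2


class TestExacerbations:
    @staticmethod
    def _mediated(n=10000, seed=16, direct=0.0):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal(n)
        lung = -0.8 * s + 0.6 * rng.standard_normal(n)  # score worsens lung function
        lung2 = -0.6 * s + 0.8 * rng.standard_normal(n)
        lin = -1.2 + 1.5 * (-lung) + direct * s
        ph = pd.DataFrame({
            "age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n),
            "pack_years": rng.gamma(2, 12, n),
            "fev1_pct_pred": 90 + 13 * lung, "fev1_fvc": 0.73 + 0.06 * lung2,
            "frequent_exacerbations": rng.binomial(1, 1 / (1 + np.exp(-lin))).astype(float),
            "severe_exacerbations": rng.binomial(1, 1 / (1 + np.exp(-lin - 0.5))).astype(float),
        })
        return ph, s

    def test_adjustment_attenuates_mediated_association(self):
        ph, s = self._mediated()
        res = exacerbation_models(ph, s)
        base, adj = res["frequent_exacerbations"]
        assert base.estimate > 0 and base.p < 0.05
        assert abs(adj.estimate) < 0.5 * abs(base.estimate)

    def test_unlinked_score_is_null(self):
        ph, _ = self._mediated(seed=17)
        rng = np.random.default_rng(18)
        noise = rng.standard_normal(len(ph))
        res = exacerbation_models(ph, noise)
        base, adj = res["frequent_exacerbations"]
        assert base.p > 0.01 and adj.p > 0.01

    def test_both_outcomes_reported_independently(self):
        ph, s = self._mediated(seed=19)
        res = exacerbation_models(ph, s)
        assert set(res) == {"frequent_exacerbations", "severe_exacerbations"}
        for base, adj in res.values():
            assert base.model != adj.model

    def test_missing_lung_function_is_error(self):
        ph, s = self._mediated(seed=20)
        with pytest.raises(ValueError, match="fev1_fvc"):
            exacerbation_models(ph.drop(columns=["fev1_fvc"]), s)
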