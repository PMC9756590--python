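"""Initial-decision logistic variants: screening, fitting, CV accuracy."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from trialpref import initial_decision as idm
from trialpref.cohort import dummy_matrix, ordinal_codes, sample_covariates


def _logit_oracle_2param(y, x, step=1e-3):
    """Coarse-to-fine exhaustive grid maximisation of the 2-parameter
    log-likelihood, independent of the Newton fitting path."""

    def ll(a, b):
        eta = a + b * x
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    lo_a, hi_a, lo_b, hi_b = -4.0, 4.0, -4.0, 4.0
    width = 0.1
    best = None
    while width >= step:
        aa = np.arange(lo_a, hi_a + width / 2, width)
        bb = np.arange(lo_b, hi_b + width / 2, width)
        vals = np.array([[ll(a, b) for b in bb] for a in aa])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        best = (aa[i], bb[j])
        lo_a, hi_a = best[0] - 2 * width, best[0] + 2 * width
        lo_b, hi_b = best[1] - 2 * width, best[1] + 2 * width
        width /= 10.0
    return best


class TestScreen:
    def test_identical_columns_second_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 200).astype(float)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.integers(0, 2, 200)})
        kept, report = idm.screen_collinearity(X)
        assert list(kept.columns) == ["a", "c"]
        row = report.query("col_a == 'a' and col_b == 'b'").iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["dropped"]

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.integers(0, 2, size=(1000, 5)).astype(float))
        X.columns = [f"x{i}" for i in range(5)]
        kept, report = idm.screen_collinearity(X)
        assert list(kept.columns) == list(X.columns)
        assert not report["dropped"].any()

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"ok": [0.0, 1, 0, 1], "flat": [1.0, 1, 1, 1]})
        with pytest.raises(idm.ModelError, match="flat"):
            idm.screen_collinearity(X)

    def test_copula_correlation_reported_below_threshold(self, big_covariates):
        codes = ordinal_codes(big_covariates).astype(float)
        kept, report = idm.screen_collinearity(codes)
        row = report.query("col_a == 'country' and col_b == 'age_group'").iloc[0]
        assert row["r"] == pytest.approx(0.63, abs=0.05)
        assert row["magnitude"] == "large"
        assert not row["dropped"]
        assert list(kept.columns) == ["country", "age_group", "employment"]


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        y = np.zeros(1000)
        y[:710] = 1.0
        fit = idm.fit_logit(y, pd.DataFrame(index=range(1000)))
        assert fit.coefficients["const"] == pytest.approx(logit(0.71), abs=1e-6)
        # BIC identity with k = 1
        assert fit.bic == pytest.approx(
            np.log(1000) - 2 * fit.log_likelihood, abs=1e-9
        )

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 400).astype(float)
        y = (rng.random(400) < expit(-0.4 + 1.1 * x)).astype(float)
        fit = idm.fit_logit(y, pd.DataFrame({"x": x}))
        a, b = _logit_oracle_2param(y, x)
        assert fit.coefficients["const"] == pytest.approx(a, abs=1e-2)
        assert fit.coefficients["x"] == pytest.approx(b, abs=1e-2)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        n = 5000
        X = pd.DataFrame(
            {
                "x1": rng.integers(0, 2, n).astype(float),
                "x2": rng.integers(0, 2, n).astype(float),
            }
        )
        beta = {"const": -0.3, "x1": 0.8, "x2": -0.5}
        eta = beta["const"] + X["x1"] * beta["x1"] + X["x2"] * beta["x2"]
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = idm.fit_logit(y, X)
        for name, true_val in beta.items():
            z = abs(fit.coefficients[name] - true_val) / fit.standard_errors[name]
            assert z < 3.0

    def test_duplicated_data_halves_variance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 300).astype(float)
        y = (rng.random(300) < expit(0.3 + 0.5 * x)).astype(float)
        X = pd.DataFrame({"x": x})
        single = idm.fit_logit(y, X)
        double = idm.fit_logit(
            np.concatenate([y, y]), pd.concat([X, X], ignore_index=True)
        )
        assert double.coefficients["x"] == pytest.approx(
            single.coefficients["x"], abs=1e-7
        )
        assert double.standard_errors["x"] ** 2 == pytest.approx(
            single.standard_errors["x"] ** 2 / 2, rel=1e-5
        )

    def test_perfect_separation_raises(self):
        y = np.array([0.0, 0, 0, 1, 1, 1] * 5)
        X = pd.DataFrame({"x": y})
        with pytest.raises(idm.ModelError):
            idm.fit_logit(y, X)

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 100).astype(float)
        y = rng.integers(0, 2, 100).astype(float)
        X = pd.DataFrame({"a": x, "b": 1 - x})  # a + b = const
        with pytest.raises(idm.ModelError, match="rank"):
            idm.fit_logit(y, X)

    def test_star_codes(self):
        assert idm.star_code(0.005) == "***"
        assert idm.star_code(0.03) == "**"
        assert idm.star_code(0.07) == "*"
        assert idm.star_code(0.2) == ""


class TestCrossValidation:
    def test_perfect_predictor_scores_100(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 300).astype(float)
        pct, _ = idm.cv_predictive_validity(y, pd.DataFrame({"x": y}), rng=1)
        assert pct == 100.0

    def test_noise_covariates_score_near_chance(self):
        rng = np.random.default_rng(5)
        n = 2000
        y = np.tile([0.0, 1.0], n // 2)
        X = pd.DataFrame(rng.integers(0, 2, size=(n, 3)).astype(float))
        X.columns = ["a", "b", "c"]
        pct, _ = idm.cv_predictive_validity(y, X, rng=2)
        assert pct == pytest.approx(50.0, abs=5.0)

    def test_majority_rule_accuracy_for_uninformative_model(self):
        rng = np.random.default_rng(6)
        n = 2000
        y = np.zeros(n)
        y[: int(0.71 * n)] = 1.0
        rng.shuffle(y)
        X = pd.DataFrame({"noise": rng.integers(0, 2, n).astype(float)})
        pct, _ = idm.cv_predictive_validity(y, X, rng=3)
        assert pct == pytest.approx(71.0, abs=3.0)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(8)
        n = 500
        X = pd.DataFrame(rng.integers(0, 2, size=(n, 4)).astype(float))
        X.columns = ["a", "b", "c", "d"]
        y = (rng.random(n) < expit(0.5 * X["a"] - 0.7 * X["c"])).astype(float)
        p1, _ = idm.cv_predictive_validity(y, X, rng=42)
        p2, _ = idm.cv_predictive_validity(y, X[["d", "c", "b", "a"]], rng=42)
        assert p1 == p2

    def test_fewer_rows_than_folds_raises(self):
        with pytest.raises(idm.ModelError):
            idm.cv_predictive_validity(
                np.array([0.0, 1.0]), pd.DataFrame({"x": [0.0, 1.0]})
            )


class TestCompareVariants:
    def test_three_fits_with_bic_identity(self, small_cohort):
        decisions = (
            small_cohort.responses.query("task_index == 0")
            .sort_values("respondent_id")["decision"]
            .to_numpy()
        )
        fits, table = idm.compare_variants(
            small_cohort.covariates, decisions, rng=0
        )
        assert set(fits) == set(idm.VARIANTS)
        assert len(table) == 3
        for fit in fits.values():
            k = len(fit.coefficients)
            assert fit.bic == pytest.approx(
                k * np.log(fit.n_obs) - 2 * fit.log_likelihood, abs=1e-9
            )
            assert 0.0 <= fit.predictive_validity_pct <= 100.0

    def test_variant_column_sets_follow_reporting_layout(self):
        m2 = set(idm.VARIANT_COLUMNS["model2_disease_country"])
        m3 = set(idm.VARIANT_COLUMNS["model3_except_disease_country"])
        assert "country_china" in m2 and "depression" in m2
        assert not m3 & set(idm.DISEASE_DUMMIES)
        assert not m3 & set(idm.COUNTRY_DUMMIES)
        # characteristics reported only under the all-variables variant
        assert "covid_vaccine" not in m3 and "qol_ge8" not in m3
        assert "survey_version_2" in m3 and "high_altruism" in m3

    def test_disease_only_signal_favors_model2(self):
        rng = np.random.default_rng(21)
        cov = sample_covariates(n=1500, rng=rng)
        D = dummy_matrix(cov)
        eta = -0.5 + 1.6 * D["depression"] + 1.4 * D["conditions_ge3"] - 1.2 * D["heart_disease"]
        y = (rng.random(len(D)) < expit(eta)).astype(float)
        _, table = idm.compare_variants(cov, y, rng=1)
        best = table.loc[table["bic"].idxmin(), "variant"]
        assert best == "model2_disease_country"

    def test_empty_variant_rejected(self, small_cohort):
        decisions = np.ones(300)
        with pytest.raises(idm.ModelError, match="zero covariates"):
            idm.compare_variants(
                small_cohort.covariates, decisions, variants={"empty": []}
            )

    def test_missing_columns_listed(self, small_cohort):
        decisions = (
            small_cohort.responses.query("task_index == 0")["decision"].to_numpy()
        )
        with pytest.raises(idm.ModelError, match="no_such_dummy"):
            idm.compare_variants(
                small_cohort.covariates,
                decisions,
                variants={"broken": ["female", "no_such_dummy"]},
            )
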