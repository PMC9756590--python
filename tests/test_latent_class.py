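"""Latent-class switch model: likelihood, EM, selection, reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from trialpref import latent_class as lc
from trialpref.trial_design import attribute_index, load_schema


def make_data(switches, codes, K=17):
    names = ("transport",) + tuple(f"attr{k}" for k in range(1, K))
    return lc.LCLData(
        switches=np.asarray(switches),
        codes=np.asarray(codes),
        attribute_names=names,
        respondent_ids=np.arange(len(switches)),
    )


def simulate_lcl(n, pi1, alphas, betas, rng):
    """Draw directly from the class-mixture switch model (independent of the
    cohort generator)."""
    K = betas.shape[1] + 1
    cls = (rng.random(n) >= pi1).astype(int)  # 0 = class 1, 1 = class 2
    codes = np.array([rng.choice(K, size=5, replace=False) for _ in range(n)])
    eta = np.concatenate([alphas[:, None], alphas[:, None] + betas], axis=1)
    p = expit(eta[cls[:, None], codes])
    switches = (rng.random((n, 5)) < p).astype(int)
    return make_data(switches, codes, K=K), cls


class TestBuildData:
    def test_switch_coding_from_responses(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        assert data.switches.shape == (300, 5)
        # cross-check one respondent by hand
        r = small_cohort.responses.query("respondent_id == 0").sort_values(
            "task_index"
        )
        init = r.iloc[0]["decision"]
        manual = (r.iloc[1:]["decision"] != init).astype(int).to_numpy()
        assert (data.switches[0] == manual).all()

    def test_all_same_decisions_give_zero_switches(self, schema):
        rows = []
        for t in range(6):
            rows.append(
                {
                    "respondent_id": 0,
                    "task_index": t,
                    "modified_attribute": "" if t == 0 else f"m{t}",
                    "decision": 1,
                }
            )
        df = pd.DataFrame(rows)
        df.loc[df.task_index > 0, "modified_attribute"] = [
            "payment", "transport", "time_away", "childcare", "concierge",
        ]
        data = lc.build_lcl_data(df)
        assert data.switches.sum() == 0

    def test_wrong_followup_count_rejected(self, small_cohort):
        broken = small_cohort.responses.iloc[:-1]
        with pytest.raises(lc.LCLError, match="5 follow-ups"):
            lc.build_lcl_data(broken)

    def test_missing_decision_rejected(self, small_cohort):
        broken = small_cohort.responses.copy()
        broken.loc[3, "decision"] = np.nan
        with pytest.raises(lc.LCLError, match="missing decision"):
            lc.build_lcl_data(broken)


class TestLoglik:
    def test_matches_bruteforce_mixture_sum(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n, C, K = 4, 3, 6
            codes = np.array(
                [rng.choice(K, size=5, replace=False) for _ in range(n)]
            )
            switches = rng.integers(0, 2, size=(n, 5))
            data = make_data(switches, codes, K=K)
            pi = rng.dirichlet(np.ones(C))
            alphas = rng.normal(size=C)
            betas = rng.normal(size=(C, K - 1))
            # brute force: plain product of Bernoulli terms per class
            total = 0.0
            for i in range(n):
                mix = 0.0
                for c in range(C):
                    prod = 1.0
                    for t in range(5):
                        k = codes[i, t]
                        eta = alphas[c] + (betas[c, k - 1] if k > 0 else 0.0)
                        p = 1.0 / (1.0 + np.exp(-eta))
                        prod *= p if switches[i, t] else (1.0 - p)
                    mix += pi[c] * prod
                total += np.log(mix)
            assert lc.lcl_loglik(pi, alphas, betas, data) == pytest.approx(
                total, abs=1e-12
            )

    def test_single_class_collapses_to_pooled_bernoulli(self):
        rng = np.random.default_rng(1)
        codes = np.array([rng.choice(17, size=5, replace=False) for _ in range(6)])
        switches = rng.integers(0, 2, size=(6, 5))
        data = make_data(switches, codes)
        alphas = np.array([-0.3])
        betas = rng.normal(size=(1, 16))
        eta = np.concatenate([alphas, alphas + betas[0]])[codes]
        pooled = np.sum(
            switches * np.log(expit(eta)) + (1 - switches) * np.log(1 - expit(eta))
        )
        assert lc.lcl_loglik([1.0], alphas, betas, data) == pytest.approx(
            pooled, abs=1e-10
        )

    def test_invalid_shares_rejected(self):
        data = make_data(np.zeros((2, 5), int), np.tile(np.arange(5), (2, 1)))
        with pytest.raises(lc.LCLError, match="simplex"):
            lc.lcl_loglik([0.7, 0.7], [0.0, 0.0], np.zeros((2, 16)), data)


class TestFit:
    def test_one_class_equals_pooled_logit(self, small_cohort, schema):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 1, n_starts=1, rng=0, compute_se=False)
        # independent route: statsmodels logistic on the indicator encoding
        X = np.zeros((data.n_respondents * 5, 16))
        flat_codes = data.codes.ravel()
        mask = flat_codes > 0
        X[np.nonzero(mask)[0], flat_codes[mask] - 1] = 1.0
        res = sm.Logit(data.switches.ravel(), sm.add_constant(X)).fit(
            method="newton", disp=False, tol=1e-12
        )
        assert fit.class_shares[0] == pytest.approx(1.0)
        assert fit.alphas[0] == pytest.approx(res.params[0], abs=1e-6)
        np.testing.assert_allclose(fit.betas[0], res.params[1:], atol=1e-6)

    def test_em_loglik_monotone(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 3, n_starts=3, rng=5, compute_se=False)
        for trace in fit.loglik_trace:
            diffs = np.diff(trace)
            assert diffs.min() >= -1e-8 * max(1.0, abs(trace[-1]))

    def test_well_separated_recovery_and_posterior(self):
        rng = np.random.default_rng(9)
        alphas = np.array([1.0, -3.0])
        betas = np.zeros((2, 16))
        betas[0, :8] = 1.5
        betas[1, 8:] = 2.0
        data, cls = simulate_lcl(2000, 0.35, alphas, betas, rng)
        fit = lc.fit_lcl(data, 2, n_starts=8, rng=1, compute_se=False)
        assert fit.class_shares[0] == pytest.approx(0.35, abs=0.03)
        W = lc.posterior_membership(fit, data)
        assert W.max(axis=1).mean() > 0.9
        # modal assignment should track the generating class
        agreement = (W.argmax(axis=1) == cls).mean()
        assert max(agreement, 1 - agreement) > 0.9

    def test_same_seed_same_fit(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        f1 = lc.fit_lcl(data, 2, n_starts=4, rng=3, compute_se=False)
        f2 = lc.fit_lcl(data, 2, n_starts=4, rng=3, compute_se=False)
        np.testing.assert_array_equal(f1.class_shares, f2.class_shares)
        np.testing.assert_array_equal(f1.betas, f2.betas)

    def test_classes_ordered_by_share(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 2, n_starts=4, rng=3, compute_se=False)
        assert fit.class_shares[0] <= fit.class_shares[1]

    def test_bic_identity(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 2, n_starts=2, rng=0, compute_se=False)
        k = 1 + 2 * 17
        assert fit.bic == pytest.approx(
            k * np.log(300) - 2 * fit.log_likelihood, abs=1e-9
        )

    def test_more_classes_than_respondents_rejected(self):
        data = make_data(np.zeros((3, 5), int), np.tile(np.arange(5), (3, 1)))
        with pytest.raises(lc.LCLError):
            lc.fit_lcl(data, 4, n_starts=1, rng=0)


class TestSelection:
    def test_single_candidate_returned(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit, table = lc.select_n_classes(data, [2], n_starts=2, rng=0,
                                         compute_se=False)
        assert fit.n_classes == 2
        assert len(table) == 1

    def test_empty_range_rejected(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        with pytest.raises(lc.LCLError):
            lc.select_n_classes(data, [], rng=0)


class TestReporting:
    def test_odds_ratio_exp_mapping(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 2, n_starts=2, rng=1, compute_se=False)
        fit.betas[0, 0] = np.log(2.0)
        fit.beta_se = np.full_like(fit.betas, 0.1)
        table = lc.odds_ratios(fit)
        row = table[(table["class"] == 1) & (table.attribute == fit.attribute_names[1])]
        assert row.iloc[0]["odds_ratio"] == pytest.approx(2.0)
        ref = table[(table["class"] == 1) & (table.attribute == "transport")]
        assert ref.iloc[0]["odds_ratio"] == 1.0
        assert (table["ci_low"] <= table["odds_ratio"]).all()
        assert (table["odds_ratio"] <= table["ci_high"]).all()

    def test_posterior_rows_sum_to_one(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 2, n_starts=2, rng=2, compute_se=False)
        W = lc.posterior_membership(fit, data)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)

    def test_one_class_posterior_all_ones(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 1, n_starts=1, rng=0, compute_se=False)
        np.testing.assert_allclose(lc.posterior_membership(fit, data), 1.0)

    def test_identical_classes_posterior_equals_shares(self):
        data = make_data(
            np.array([[0, 1, 0, 0, 1]] * 4), np.tile(np.arange(5), (4, 1))
        )
        fit = lc.LCLFit(
            n_classes=2,
            class_shares=np.array([0.3, 0.7]),
            alphas=np.array([-0.5, -0.5]),
            betas=np.zeros((2, 16)),
            log_likelihood=0.0,
            bic=0.0,
            posterior=np.empty((4, 2)),
            attribute_names=data.attribute_names,
            n_starts=0,
        )
        W = lc.posterior_membership(fit, data)
        np.testing.assert_allclose(W, np.tile([0.3, 0.7], (4, 1)), atol=1e-12)

    def test_switch_summary_degenerate_cases(self):
        codes = np.tile(np.arange(5), (4, 1))
        none = lc.switch_summary(make_data(np.zeros((4, 5), int), codes))
        assert none.pct_tasks_switched == 0.0
        assert none.pct_never_switched == 100.0
        every = lc.switch_summary(make_data(np.ones((4, 5), int), codes))
        assert every.pct_always_switched == 100.0

    def test_per_class_rates_contrast(self, small_cohort):
        data = lc.build_lcl_data(small_cohort.responses)
        fit = lc.fit_lcl(data, 2, n_starts=4, rng=4, compute_se=False)
        summary = lc.switch_summary(data, fit.posterior)
        # class 1 (smaller share) switches far more than class 2
        assert summary.per_class_switch_rates[0] > summary.per_class_switch_rates[1]
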