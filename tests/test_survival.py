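import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from irgpi import (
    CohortSpec,
    ValidationError,
    build_pairs,
    cox_fit,
    km_curve,
    km_survival_at,
    lasso_cox_select,
    logrank_test,
    simulate_cohort,
    td_roc,
    univariate_screen,
)
from irgpi.survival import breslow_loglik, lasso_cox_path


def _random_survival(seed, n=50, p=2, censor=0.3, beta=(0.6, -0.4)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    t = rng.exponential(np.exp(-(X @ np.asarray(beta)[:p])))
    e = (rng.uniform(size=n) > censor).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return t, e, X


def naive_partial_loglik(beta, X, time, event):
    """Independent O(n^2) Cox log partial likelihood (untied times)."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


class TestLogrank:
    def test_hand_computed_four_subjects(self):
        # group A events at 1,2; group B at 3,4; O_A=2, E_A=0.8333, V=0.4722
        r = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert r.chi2 == pytest.approx(2.882, abs=1e-3)

    def test_identical_groups_symmetric(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        r = logrank_test(t, e, ["a"] * 3 + ["b"] * 3)
        assert r.chi2 == 0.0
        assert r.p == 1.0

    def test_all_censored_degenerate(self):
        r = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert r.chi2 == 0.0
        assert r.p == 1.0

    def test_label_swap_invariance(self):
        t, e, _ = _random_survival(1, n=40)
        g = np.repeat([0, 1], 20)
        assert logrank_test(t, e, g).chi2 == pytest.approx(
            logrank_test(t, e, 1 - g).chi2
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines(self, seed):
        from lifelines.statistics import logrank_test as ll_logrank

        t, e, _ = _random_survival(seed, n=80)
        g = np.random.default_rng(seed).integers(0, 2, 80)
        ours = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_stays_one(self):
        assert km_survival_at([5, 6, 7], [0, 0, 0], t=10) == 1.0

    def test_single_subject_event(self):
        assert km_survival_at([1.0], [1], t=1.0) == 0.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        t, e, _ = _random_survival(3, n=60)
        km = km_curve(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for ti in km.index:
            assert km.loc[ti, "survival"] == pytest.approx(
                float(ref.survival_function_at_times(ti).iloc[0]), rel=1e-9
            )


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        t, e, X = _random_survival(0)
        X[:, 1] = 3.0
        with pytest.raises(ValidationError, match="degenerate covariate"):
            cox_fit(t, e, X)

    def test_collinear_covariates_rejected(self):
        t, e, X = _random_survival(0)
        X2 = np.hstack([X, X[:, [0]]])
        with pytest.raises(ValidationError, match="collinear|rank"):
            cox_fit(t, e, X2)

    def test_zero_events_rejected(self):
        t, e, X = _random_survival(0)
        with pytest.raises(ValidationError, match="event"):
            cox_fit(t, np.zeros_like(e), X)

    def test_negated_covariate_flips_sign_exactly(self):
        t, e, X = _random_survival(4)
        a = cox_fit(t, e, X).summary["coef"].to_numpy()
        b = cox_fit(t, e, -X).summary["coef"].to_numpy()
        np.testing.assert_allclose(a, -b, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_maximiser(self, seed):
        t, e, X = _random_survival(seed, n=40)
        fit = cox_fit(t, e, X)
        res = optimize.minimize(
            lambda b: -naive_partial_loglik(b, X, t, e),
            x0=np.zeros(2),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(fit.summary["coef"].to_numpy(), res.x, atol=1e-6)

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        t, e, X = _random_survival(7, n=80)
        t = np.ceil(t * 4) / 4  # force ties
        fit = cox_fit(t, e, X, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron ties
        np.testing.assert_allclose(
            fit.summary["coef"].to_numpy(), ref.params_.to_numpy(), atol=2e-5
        )
        np.testing.assert_allclose(
            fit.summary["se"].to_numpy(),
            ref.standard_errors_.to_numpy(),
            atol=2e-4,
        )

    def test_breslow_ties_match_brute_force(self):
        def naive_breslow(beta, X, time, event):
            eta = X @ np.asarray(beta, dtype=float)
            ll = 0.0
            for i in np.flatnonzero(event):
                ll += eta[i] - np.log(np.sum(np.exp(eta[time >= time[i]])))
            return ll

        t, e, X = _random_survival(7, n=60)
        t = np.ceil(t * 4) / 4  # force ties
        fit = cox_fit(t, e, X, ties="breslow")
        res = optimize.minimize(
            lambda b: -naive_breslow(b, X, t, e),
            x0=np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(fit.summary["coef"].to_numpy(), res.x, atol=1e-6)

    def test_separation_warns_and_caps(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])[:, None]
        with pytest.warns(RuntimeWarning, match="monotone|separation"):
            fit = cox_fit(t, e, x)
        assert np.isfinite(fit.summary["coef"].iloc[0])


class TestUnivariateScreen:
    def _cohort_matrix(self, seed=17, n=300):
        spec = CohortSpec(n_samples=n, n_genes=30, seed=seed)
        expr, clin, _ = simulate_cohort(spec)
        pm = build_pairs(expr, expr.index)
        return pm, clin["time"].to_numpy(), clin["event"].to_numpy()

    def test_alpha_one_retains_every_pair(self):
        pm, t, e = self._cohort_matrix()
        kept, table = univariate_screen(pm, t, e, alpha=1.0)
        assert len(kept.pairs) == len(pm.pairs)

    def test_strongly_prognostic_pair_retained(self):
        # planted beta=2 on a fair-coin indicator at n=300
        spec = CohortSpec(n_samples=300, n_genes=10,
                          planted_pairs=[("G0001", "G0002", 2.0)], seed=23)
        expr, clin, _ = simulate_cohort(spec)
        pm = build_pairs(expr, expr.index)
        kept, _ = univariate_screen(
            pm, clin["time"].to_numpy(), clin["event"].to_numpy(), alpha=0.05
        )
        assert ("G0001", "G0002") in kept.pairs

    def test_no_survivor_raises(self):
        pm, t, e = self._cohort_matrix(seed=29, n=60)
        rng = np.random.default_rng(0)
        t = rng.exponential(300, size=len(t))  # survival decoupled from pairs
        with pytest.raises(ValidationError, match="alpha"):
            univariate_screen(pm, t, e, alpha=1e-12)


class TestLassoCox:
    def _fit_inputs(self, seed=31, n=200):
        spec = CohortSpec(n_samples=n, n_genes=24, seed=seed)
        expr, clin, _ = simulate_cohort(spec)
        pm = build_pairs(expr, expr.index)
        return pm, clin["time"].to_numpy(float), clin["event"].to_numpy(int)

    def test_path_starts_all_zero_and_cv_improves(self):
        pm, t, e = self._fit_inputs()
        path, sig = lasso_cox_select(pm, t, e, k_folds=5, seed=1)
        assert np.all(path.coefs[:, 0] == 0.0)
        k_min = int(np.argmin(np.abs(path.alphas - path.alpha_min)))
        assert path.cv_mean[k_min] <= path.cv_mean[0]
        assert len(sig.pairs) >= 1
        assert all(p.coefficient != 0 for p in sig.pairs)

    def test_unpenalised_limit_matches_cox_fit(self):
        rng = np.random.default_rng(5)
        n = 120
        X = rng.integers(0, 2, size=(n, 3)).astype(float)
        t = rng.exponential(np.exp(-(X @ [0.8, -0.5, 0.3])))
        e = np.ones(n, int)
        path = lasso_cox_path(
            X, t, e, feature_names=list("abc"), k_folds=4, seed=0,
            alphas=[0.25, 0.01, 1e-7],
        )
        beta_small = path.coefs[:, -1]  # smallest penalty on the grid
        ref = cox_fit(t, e, X, names=list("abc")).summary["coef"].to_numpy()
        np.testing.assert_allclose(beta_small, ref, atol=1e-4)

    def test_1se_rule_never_denser_than_min(self):
        pm, t, e = self._fit_inputs(seed=37)
        path, _ = lasso_cox_select(pm, t, e, k_folds=5, seed=2)
        assert path.alpha_1se >= path.alpha_min
        nz = (path.coefs != 0).sum(axis=0)
        k_min = int(np.argmin(np.abs(path.alphas - path.alpha_min)))
        k_1se = int(np.argmin(np.abs(path.alphas - path.alpha_1se)))
        assert nz[k_1se] <= nz[k_min]

    def test_breslow_loglik_matches_naive(self):
        t, e, X = _random_survival(11, n=40)
        beta = np.array([0.3, -0.2])
        assert breslow_loglik(beta, X, t, e) == pytest.approx(
            naive_partial_loglik(beta, X, t, e), rel=1e-10
        )


class TestTimeDependentROC:
    def test_no_censoring_reduces_to_mann_whitney_auc(self):
        from scipy.stats import mannwhitneyu

        for seed in range(4):
            rng = np.random.default_rng(seed)
            s = rng.normal(size=60)
            t = rng.uniform(10, 1000, 60)
            e = np.ones(60, int)
            roc = td_roc(s, t, e, t_eval=500.0)
            cases = t <= 500.0
            mw = mannwhitneyu(s[cases], s[~cases]).statistic / (
                cases.sum() * (~cases).sum()
            )
            assert roc.auc == pytest.approx(mw, abs=1e-9)

    def test_perfect_separation_youden_one_cutoff_between_clusters(self):
        s = np.array([0.1, 0.2, 0.3, 2.1, 2.2, 2.3])
        t = np.array([900, 950, 800, 30, 40, 50.0])
        e = np.ones(6, int)
        roc = td_roc(s, t, e, t_eval=365.0)
        assert roc.youden == pytest.approx(1.0)
        assert 0.3 < roc.cutoff < 2.1

    def test_no_events_by_horizon_rejected(self):
        s = np.linspace(0, 1, 10)
        t = np.full(10, 500.0)
        e = np.ones(10, int)
        with pytest.raises(ValidationError, match="no cases"):
            td_roc(s, t, e, t_eval=100.0)

    def test_horizon_beyond_follow_up_rejected(self):
        with pytest.raises(ValidationError, match="follow-up"):
            td_roc([1.0, 2.0], [10.0, 20.0], [1, 1], t_eval=30.0)

    def test_censoring_aware_auc_reasonable_for_prognostic_score(self):
        spec = CohortSpec(n_samples=400, n_genes=12, seed=41)
        expr, clin, truth = simulate_cohort(spec)
        roc = td_roc(
            truth["eta"], clin["time"].to_numpy(), clin["event"].to_numpy(),
            t_eval=365.0,
        )
        assert 0.6 < roc.auc <= 1.0
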