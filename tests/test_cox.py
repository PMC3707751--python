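import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from coxsig import (CoxLasso, CoxLassoCV, CoxPH, cox_partial_loglik,
                    default_lambda_grid, fit_cox, fit_cox_lasso,
                    kaplan_meier, lambda_max, linear_predictor,
                    select_lambda_cv)
from conftest import random_survival


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def breslow_loglik_oracle(beta, X, times, events):
    """Risk-set enumeration of the Breslow partial likelihood."""
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = X @ beta
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


def lasso_objective_oracle(X, times, events, lam):
    """Maximize l(beta) - lam*||beta||_1 via the split-variable convex
    reformulation with L-BFGS-B."""
    p = X.shape[1]

    def neg(z):
        b = z[:p] - z[p:]
        return -(cox_partial_loglik(b, X, times, events, ties="breslow")
                 - lam * z.sum())

    best = None
    for start in (np.full(2 * p, 0.01), np.full(2 * p, 0.3)):
        res = minimize(neg, start, method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * p,
                       options=dict(maxiter=20000, ftol=1e-15, gtol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

class TestPartialLoglik:
    def test_null_beta_all_events(self):
        # l(0) = -sum log(risk-set size) = -(ln3 + ln2 + ln1) = -ln6
        X = np.zeros((3, 1)) + [[0.0], [1.0], [2.0]]
        ll = cox_partial_loglik([0.0], X, [1, 2, 3], [1, 1, 1])
        assert ll == pytest.approx(-np.log(6))

    def test_censored_subject_contributes_no_event_term(self):
        X = np.array([[0.0], [1.0], [2.0]])
        ll = cox_partial_loglik([0.0], X, [1, 2, 3], [1, 0, 1])
        assert ll == pytest.approx(-np.log(3) - np.log(1))

    def test_matches_hand_breslow_enumeration(self):
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, 1.0, 0.0, 1.0])
        ours = cox_partial_loglik([1.0], X, t, e, ties="breslow")
        assert ours == pytest.approx(
            breslow_loglik_oracle([1.0], X, t, e), abs=1e-12)

    def test_matches_oracle_on_random_instances_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 15))
            X = rng.normal(size=(n, 2))
            t, e = random_survival(rng, n)
            beta = rng.normal(size=2)
            assert cox_partial_loglik(beta, X, t, e, ties="breslow") == \
                pytest.approx(breslow_loglik_oracle(beta, X, t, e),
                              abs=1e-10)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 20
        X = rng.normal(size=(n, 2))
        t = rng.permutation(np.arange(1.0, n + 1))
        e = (rng.random(n) > 0.3).astype(float)
        e[0] = 1.0
        beta = [0.4, -0.3]
        assert cox_partial_loglik(beta, X, t, e, "breslow") == \
            pytest.approx(cox_partial_loglik(beta, X, t, e, "efron"),
                          abs=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_partial_loglik([0.0], np.ones((3, 1)), [1, 2, 3], [0, 0, 0])


# ---------------------------------------------------------------------------
# Newton fitting
# ---------------------------------------------------------------------------

class TestFitCox:
    def test_tied_pair_gives_zero_coefficient(self):
        fit = fit_cox(np.array([[1.0], [0.0]]), [5.0, 5.0], [1, 1],
                      ties="breslow")
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_monotone_likelihood_flagged(self):
        # event ordered exactly by covariate: likelihood increases in beta
        fit = fit_cox(np.array([[1.0], [0.0]]), [1.0, 2.0], [1, 1])
        assert fit.diverged[0]
        assert abs(fit.coef[0]) >= 14.9

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_scalar_optimizer_oracle(self, ties, rng):
        X = np.array([[1.0], [0.0], [1.0], [1.0], [0.0], [0.0]])
        t = np.array([3.0, 5.0, 7.0, 2.0, 9.0, 4.0])
        e = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        res = minimize_scalar(
            lambda b: -cox_partial_loglik([b], X, t, e, ties),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        fit = fit_cox(X, t, e, ties=ties)
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 150
        X = rng.normal(size=(n, 3))
        risk = np.exp(X @ np.array([0.5, -0.5, 0.0]))
        t = rng.exponential(1 / risk)
        c = rng.exponential(2, n)
        times, events = np.minimum(t, c), (t <= c).astype(float)
        fit = fit_cox(X, times, events, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = times, events
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, ll.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values,
                                   atol=1e-4)
        assert fit.loglik == pytest.approx(ll.log_likelihood_, abs=1e-5)

    def test_two_group_exponential_recovers_log_hr(self, rng):
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        true = 0.7
        t = rng.exponential(np.exp(-true * x))
        c = rng.exponential(1.5, n)
        fit = fit_cox(x[:, None], np.minimum(t, c), (t <= c).astype(float))
        assert fit.coef[0] == pytest.approx(true, rel=0.1)

    def test_hazard_ratio_identities(self, rng):
        X = rng.normal(size=(60, 2))
        t, e = random_survival(rng, 60)
        fit = fit_cox(X, t, e)
        np.testing.assert_allclose(fit.hazard_ratios, np.exp(fit.coef))
        assert (fit.ci_low < fit.hazard_ratios).all()
        assert (fit.hazard_ratios < fit.ci_high).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.arange(4.0)[:, None], [1, 2, 3, 4], [0, 0, 0, 0])


# ---------------------------------------------------------------------------
# L1-penalized fitting
# ---------------------------------------------------------------------------

class TestFitCoxLasso:
    def test_zero_penalty_equals_newton_fit(self, rng):
        X = rng.normal(size=(50, 4))
        t, e = random_survival(rng, 50)
        unpen = fit_cox(X, t, e, ties="breslow")
        lasso = fit_cox_lasso(X, t, e, lam=0.0)
        np.testing.assert_allclose(lasso.coef, unpen.coef, atol=1e-5)

    def test_at_lambda_max_all_zero(self, rng):
        X = rng.normal(size=(40, 5))
        t, e = random_survival(rng, 40)
        lm = lambda_max(X, t, e)
        fit = fit_cox_lasso(X, t, e, lam=lm * (1 + 1e-10))
        assert np.all(fit.coef == 0.0)
        below = fit_cox_lasso(X, t, e, lam=lm * 0.8)
        assert np.any(below.coef != 0.0)

    def test_intermediate_penalty_matches_convex_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        beta_true = np.array([0.8, -0.5, 0.0])
        t = rng.exponential(np.exp(-X @ beta_true))
        e = np.ones(20)
        lam = lambda_max(X, t, e) * 0.3
        fit = fit_cox_lasso(X, t, e, lam=lam)
        mine = fit.loglik - lam * np.abs(fit.coef).sum()
        oracle = lasso_objective_oracle(X, t, e, lam)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_kkt_conditions_at_solution(self, rng):
        from coxsig import _cd
        from coxsig._survdata import sort_survival
        X = rng.normal(size=(60, 6))
        t, e = random_survival(rng, 60)
        lam = lambda_max(X, t, e) * 0.2
        fit = fit_cox_lasso(X, t, e, lam=lam)
        _, ts, es, Xs, first = sort_survival(t, e, X)
        g, _ = _cd.breslow_grad_weights(Xs @ fit.coef, es, first)
        score = Xs.T @ g
        for j in range(6):
            if fit.coef[j] == 0.0:
                assert abs(score[j]) <= lam + 1e-5
            else:
                assert score[j] == pytest.approx(
                    lam * np.sign(fit.coef[j]), abs=1e-5)

    def test_l1_norm_monotone_in_penalty(self, rng):
        X = rng.normal(size=(80, 5))
        t, e = random_survival(rng, 80)
        grid = default_lambda_grid(lambda_max(X, t, e), n=20)
        norms = [np.abs(fit_cox_lasso(X, t, e, lam=l).coef).sum()
                 for l in grid]
        # grid is descending, so the norms must be non-decreasing
        assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_sparsity_increases_with_penalty(self, rng):
        X = rng.normal(size=(80, 8))
        t, e = random_survival(rng, 80)
        lm = lambda_max(X, t, e)
        nnz = [np.count_nonzero(fit_cox_lasso(X, t, e, lam=f * lm).coef)
               for f in (0.9, 0.3, 0.01)]
        assert nnz[0] <= nnz[1] <= nnz[2]

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_lasso(np.ones((4, 1)) * [[1], [2], [3], [4]],
                          [1, 2, 3, 4], [1, 1, 1, 1], lam=-1.0)


# ---------------------------------------------------------------------------
# cross-validated penalty choice
# ---------------------------------------------------------------------------

class TestSelectLambdaCV:
    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(100, 6))
        t, e = random_survival(rng, 100)
        a = select_lambda_cv(X, t, e, seed=7)
        b = select_lambda_cv(X, t, e, seed=7)
        assert a.chosen == b.chosen
        np.testing.assert_array_equal(a.folds, b.folds)
        np.testing.assert_allclose(a.cv_loglik, b.cv_loglik)

    def test_strong_signal_keeps_model_nonempty(self, rng):
        n = 200
        x = rng.normal(size=(n, 1)) * 1.0
        t = rng.exponential(np.exp(-x[:, 0]))
        c = rng.exponential(2, n)
        times, events = np.minimum(t, c), (t <= c).astype(float)
        cv = select_lambda_cv(x, times, events, seed=3)
        assert cv.chosen < lambda_max(x, times, events)
        est = CoxLassoCV(random_state=3).fit(x, (times, events))
        assert np.count_nonzero(est.coef_) == 1

    def test_pure_noise_selects_sparse_models(self):
        # maximum-CV penalty choice is known to loosen as the panel
        # grows; on a small panel the null model should dominate
        sparse = 0
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(200, 5))
            t = rng.exponential(1.0, 200)
            c = rng.exponential(2.0, 200)
            times, events = np.minimum(t, c), (t <= c).astype(float)
            est = CoxLassoCV(random_state=s).fit(X, (times, events))
            if np.count_nonzero(est.coef_) <= 1:
                sparse += 1
        assert sparse >= 40  # >= 80% of seeds empty or near-empty

    def test_chosen_lambda_in_grid(self, rng):
        X = rng.normal(size=(60, 4))
        t, e = random_survival(rng, 60)
        cv = select_lambda_cv(X, t, e, seed=1)
        assert cv.chosen in cv.grid
        assert len(cv.grid) == len(cv.cv_loglik)

    def test_too_few_events_for_folds_rejected(self):
        t = np.arange(1.0, 13.0)
        e = np.zeros(12)
        e[0] = 1.0  # single event cannot stratify into 10 folds
        X = np.linspace(0, 1, 12)[:, None]
        with pytest.raises(ValueError, match="zero events"):
            select_lambda_cv(X, t, e, seed=0)


# ---------------------------------------------------------------------------
# Kaplan-Meier and linear predictor
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_censoring_steps(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.at(0) == 1.0
        assert km.at(2.5) == 0.5

    def test_censoring_product_limit(self):
        # hand product-limit: S(1) = 2/3; the last subject fails -> S(3)=0
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_all_censored_is_unity(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert km.at(5) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t, e = random_survival(rng, 80)
        km = kaplan_meier(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for tt in km.event_times:
            assert km.at(tt) == pytest.approx(
                float(ref.survival_function_at_times(tt).iloc[0]))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])


class TestLinearPredictor:
    def test_zero_coefficients_zero_scores(self, rng):
        X = rng.normal(size=(30, 2))
        t, e = random_survival(rng, 30)
        fit = fit_cox_lasso(X, t, e, lam=1e9)
        np.testing.assert_array_equal(linear_predictor(fit, X),
                                      np.zeros(30))

    def test_identity_single_covariate(self, rng):
        t, e = random_survival(rng, 30)
        fit = fit_cox(np.linspace(-1, 1, 30)[:, None], t, e)
        fit.coef[:] = 1.0
        x = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(linear_predictor(fit, x), [0, 1, 2])

    def test_matches_matrix_product(self, default_cohort):
        genes = list(default_cohort.panel.os_signature)
        X = default_cohort.data[genes]
        fit = fit_cox(X, *default_cohort.survival("os"))
        np.testing.assert_allclose(linear_predictor(fit, X),
                                   X.to_numpy() @ fit.coef)

    def test_column_mismatch_rejected(self, default_cohort):
        genes = list(default_cohort.panel.os_signature)
        fit = fit_cox(default_cohort.data[genes],
                      *default_cohort.survival("os"))
        with pytest.raises(ValueError):
            linear_predictor(fit, default_cohort.data[genes[:-1]])
        with pytest.raises(ValueError):
            linear_predictor(fit, np.zeros((3, 2)))


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        est = CoxPH(ties="breslow")
        assert est.get_params()["ties"] == "breslow"
        est.set_params(ties="efron")
        assert est.ties == "efron"

    def test_clone_and_pipeline_compatible(self, rng):
        from sklearn.base import clone
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        t, e = random_survival(rng, 50)
        est = clone(CoxLasso(alpha=0.5)).fit(X, (t, e))
        assert est.coef_.shape == (3,)
        assert est.predict(X).shape == (50,)
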