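"""The eight regression strategies and their stated equivalences."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from facecolour.models import (
    FittedModel,
    fit_ols,
    fit_pcr,
    fit_plsr,
    fit_regularized,
    fit_stepwise,
    lambda_max,
    penalized_fit,
    rank_predictors,
    standardize,
)


def _design(rng, n=30, p=5, beta=None, noise=0.3):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
    )
    X = (X - X.mean()) / X.std(ddof=1)
    if beta is None:
        beta = np.zeros(p)
        beta[0] = 1.0
    y = pd.Series(X.to_numpy() @ beta + noise * rng.standard_normal(n) + 4.0,
                  index=X.index)
    return X, y


class TestStandardize:
    def test_sample_sd_convention(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, params = standardize(df)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])
        zpop, _ = standardize(df, ddof=0)
        assert np.allclose(zpop["a"], [-1.22474487, 0.0, 1.22474487])

    def test_apply_is_idempotent_on_training(self, rng):
        df = pd.DataFrame(rng.normal(5, 2, size=(20, 3)), columns=list("abc"))
        z, params = standardize(df)
        assert np.allclose(params.apply(df), z)

    def test_test_column_equal_to_train_transforms_identically(self, rng):
        df = pd.DataFrame(rng.normal(5, 2, size=(20, 2)), columns=list("ab"))
        z, params = standardize(df)
        assert np.allclose(params.apply(df.copy()), z)

    def test_zero_sd_column_named_in_error(self):
        df = pd.DataFrame({"flat": [1.0, 1.0], "ok": [0.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestOls:
    def test_exact_linear_data_zero_residuals(self, rng):
        X, y = _design(rng, noise=0.0)
        m = fit_ols(X, y)
        assert np.allclose(m.predict(X), y, atol=1e-10)

    def test_orthonormal_centred_design_closed_form(self, rng):
        # columns orthonormal and mean-zero: coefficients are exactly X^T y
        raw = rng.standard_normal((20, 4))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)
        X = pd.DataFrame(q, columns=list("abcd"))
        y = pd.Series(rng.standard_normal(20))
        m = fit_ols(X, y)
        assert np.allclose(m.coef.to_numpy(), X.to_numpy().T @ y.to_numpy(),
                           atol=1e-8)

    def test_matches_normal_equations(self, rng):
        X, y = _design(rng, n=25, p=4)
        m = fit_ols(X, y)
        D = np.column_stack([np.ones(25), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y.to_numpy())
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(m.coef.to_numpy(), beta[1:], atol=1e-8)

    def test_rank_deficient_warns_minimum_norm(self, rng):
        X, y = _design(rng, n=10, p=3)
        X["dup"] = X["x0"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = fit_ols(X, y)
        assert np.isfinite(m.coef).all()


def _greedy_aic_oracle(X, y, direction):
    """Independent re-implementation of greedy AIC stepwise using plain
    numpy least squares over explicit candidate enumeration."""
    cols = list(X.columns)
    n = len(y)

    def aic_of(subset):
        D = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in subset])
        beta, *_ = np.linalg.lstsq(D, y.to_numpy(), rcond=None)
        rss = float(((y.to_numpy() - D @ beta) ** 2).sum())
        return n * np.log(max(rss, 1e-300) / n) + 2 * (len(subset) + 2)

    current = [] if direction == "forward" else list(cols)
    cur = aic_of(current)
    while True:
        moves = []
        for c in cols:
            if direction == "forward" and c not in current:
                moves.append((aic_of(current + [c]), c))
            elif direction == "backward" and c in current:
                moves.append((aic_of([v for v in current if v != c]), c))
        if not moves:
            break
        best_aic, best_c = min(moves, key=lambda t: t[0])
        if best_aic >= cur - 1e-12:
            break
        cur = best_aic
        if direction == "forward":
            current.append(best_c)
        else:
            current.remove(best_c)
    return [c for c in cols if c in current]


class TestStepwise:
    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_matches_enumeration_oracle(self, rng, direction):
        for _ in range(5):
            X, y = _design(rng, n=40, p=5, noise=0.4)
            m = fit_stepwise(X, y, direction)
            assert m.selected == _greedy_aic_oracle(X, y, direction)

    def test_forward_finds_the_dominant_signal(self, rng):
        X, y = _design(rng, n=40, p=5, noise=0.2)
        m = fit_stepwise(X, y, "forward")
        assert m.algorithm == "SF"
        assert "x0" in m.selected
        assert m.selected[0] == "x0" or len(m.selected) <= 3

    def test_backward_removes_most_noise_variables(self, rng):
        X, y = _design(rng, n=40, p=5, noise=0.2)
        m = fit_stepwise(X, y, "backward")
        assert m.algorithm == "SB"
        assert "x0" in m.selected
        assert len(m.selected) <= 3

    def test_zero_signal_selects_little(self, rng):
        sizes = []
        for _ in range(10):
            X = pd.DataFrame(rng.standard_normal((40, 4)),
                             columns=list("abcd"))
            y = pd.Series(rng.standard_normal(40))
            sizes.append(len(fit_stepwise(X, y, "forward").selected))
        # AIC admits a pure-noise variable with prob ~0.16 each; most runs
        # stay at or near the intercept-only model
        assert np.mean(sizes) <= 1.5
        assert min(sizes) == 0

    def test_trace_records_monotone_aic(self, rng):
        X, y = _design(rng, n=40, p=5, noise=0.5)
        m = fit_stepwise(X, y, "forward")
        aics = [t["aic"] for t in m.details["trace"]]
        assert all(a2 < a1 for a1, a2 in zip(aics, aics[1:]))


class TestDimensionReduction:
    def test_pcr_all_components_equals_ols(self, rng):
        X, y = _design(rng, n=30, p=4, noise=0.5)
        ols = fit_ols(X, y)
        pcr = fit_pcr(X, y, folds=5, k_grid=[4])
        assert np.allclose(pcr.predict(X), ols.predict(X), atol=1e-6)

    def test_plsr_all_components_equals_ols(self, rng):
        X, y = _design(rng, n=30, p=4, noise=0.5)
        ols = fit_ols(X, y)
        pls = fit_plsr(X, y, folds=5, k_grid=[4])
        assert np.allclose(pls.predict(X), ols.predict(X), atol=1e-6)

    def test_plsr_single_predictor_is_simple_regression(self, rng):
        X, y = _design(rng, n=30, p=1, noise=0.5)
        pls = fit_plsr(X, y, folds=5, k_grid=[1])
        ols = fit_ols(X, y)
        assert np.allclose(pls.predict(X), ols.predict(X), atol=1e-8)

    def test_two_latent_factor_blocks_need_two_components(self, rng):
        # two disjoint loading blocks: the outcome lives in the span of the
        # top two principal components, so two components already achieve
        # (essentially) the optimal CV error; min-rule selection may wander
        # along the flat tail but never beats k = 2 by a meaningful margin
        for trial in range(5):
            f = rng.standard_normal((60, 2))
            load = np.zeros((2, 10))
            load[0, :5] = rng.uniform(0.8, 0.95, 5)
            load[1, 5:] = rng.uniform(0.8, 0.95, 5)
            X = pd.DataFrame(f @ load + 0.3 * rng.standard_normal((60, 10)))
            X.columns = [f"v{i}" for i in range(10)]
            X = (X - X.mean()) / X.std(ddof=1)
            y = pd.Series(f @ [1.0, -0.8] + 0.4 * rng.standard_normal(60))
            m = fit_pcr(X, y, folds=10, fold_seed=trial)
            cv = m.tuning["cv_rmse"]
            assert cv[2] <= 1.05 * min(cv.values())

    def test_cv_reproducible_with_fold_seed(self, rng):
        X, y = _design(rng, n=30, p=6, noise=0.5)
        m1 = fit_pcr(X, y, folds=5, fold_seed=3)
        m2 = fit_pcr(X, y, folds=5, fold_seed=3)
        assert m1.tuning == m2.tuning
        assert np.allclose(m1.coef, m2.coef)


def _en_objective(b0, b, X, y, lam, alpha):
    resid = y - b0 - X @ b
    return (
        (resid @ resid) / (2 * len(y))
        + lam * ((1 - alpha) / 2 * (b @ b) + alpha * np.abs(b).sum())
    )


class TestRegularized:
    def test_ridge_lambda_zero_equals_ols(self, rng):
        X, y = _design(rng, n=30, p=5, noise=0.4)
        ols = fit_ols(X, y)
        rr = penalized_fit(X, y, lam=0.0, alpha=0.0)
        assert np.allclose(rr.coef, ols.coef, atol=1e-6)

    def test_lasso_at_lambda_max_is_all_zero(self, rng):
        X, y = _design(rng, n=40, p=6, noise=0.4)
        lmax = lambda_max(X.to_numpy(), y.to_numpy(), alpha=1.0)
        m = penalized_fit(X, y, lam=lmax * 1.0001, alpha=1.0)
        assert (m.coef == 0).all()
        m2 = penalized_fit(X, y, lam=lmax * 0.8, alpha=1.0)
        assert (m2.coef != 0).any()

    def test_en_alpha_one_is_lasso(self, rng):
        X, y = _design(rng, n=40, p=6, noise=0.4)
        lam = 0.05
        en = penalized_fit(X, y, lam=lam, alpha=1.0)
        lasso = penalized_fit(X, y, lam=lam, alpha=1.0)
        assert np.allclose(en.coef, lasso.coef)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_minimizes_elastic_net_objective(self, rng, alpha):
        # independent oracle: direct numerical minimization of the penalty
        # objective on a tiny instance
        X, y = _design(rng, n=12, p=3, noise=0.5)
        lam = 0.1
        m = penalized_fit(X, y, lam=lam, alpha=alpha)
        xn, yn = X.to_numpy(), y.to_numpy()

        def obj(theta):
            return _en_objective(theta[0], theta[1:], xn, yn, lam, alpha)

        res = optimize.minimize(obj, np.zeros(4), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 20000})
        ours = obj(np.concatenate([[m.intercept], m.coef.to_numpy()]))
        assert ours <= res.fun + 1e-6

    def test_ridge_norm_shrinks_with_lambda(self, rng):
        X, y = _design(rng, n=30, p=5, noise=0.4)
        norms = [
            np.linalg.norm(penalized_fit(X, y, lam, 0.0).coef)
            for lam in (0.0, 0.01, 0.1, 1.0, 10.0)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lasso_support_non_increasing_along_grid(self, rng):
        X, y = _design(rng, n=40, p=8,
                       beta=np.array([1, 0.5, 0.3, 0, 0, 0, 0, 0.2]),
                       noise=0.4)
        lmax = lambda_max(X.to_numpy(), y.to_numpy(), 1.0)
        lams = np.geomspace(lmax, lmax * 1e-3, 12)
        sizes = [
            int((penalized_fit(X, y, lam, 1.0).coef != 0).sum()) for lam in lams
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_cv_fit_reproducible_and_records_tuning(self, rng):
        X, y = _design(rng, n=30, p=6, noise=0.5)
        m1 = fit_regularized(X, y, "EN", folds=5, fold_seed=9)
        m2 = fit_regularized(X, y, "EN", folds=5, fold_seed=9)
        assert m1.tuning == m2.tuning
        assert np.allclose(m1.coef, m2.coef)
        assert 0.0 <= m1.tuning["alpha"] <= 1.0
        assert m1.tuning["lambda"] > 0

    def test_rr_and_lasso_fix_alpha(self, rng):
        X, y = _design(rng, n=30, p=5, noise=0.5)
        assert fit_regularized(X, y, "RR", folds=5).tuning["alpha"] == 0.0
        assert fit_regularized(X, y, "LASSO", folds=5).tuning["alpha"] == 1.0

    def test_zero_variance_response_rejected(self, rng):
        X, _ = _design(rng, n=20, p=3)
        with pytest.raises(ValueError, match="variance"):
            fit_regularized(X, pd.Series(np.ones(20), index=X.index), "EN",
                            folds=5)


class TestRanking:
    def test_rank_by_abs_coefficient_with_zeros_rank_zero(self):
        coef = pd.Series({"a": 0.5, "b": -0.9, "c": 0.0})
        m = FittedModel("EN", 0.0, coef, selected=["a", "b"])
        r = rank_predictors(m)["rank"]
        assert r["b"] == 1 and r["a"] == 2 and r["c"] == 0

    def test_training_rmse_optimality_of_ols(self, screened_data):
        from facecolour.evaluate import rmse
        from facecolour.models import fit_all

        d = screened_data
        models = fit_all(d["Xtr"], d["ytr"], folds=10, fold_seed=0)
        ols_rmse = rmse(d["ytr"], models["OLS"].predict(d["Xtr"]))
        for name, m in models.items():
            assert ols_rmse <= rmse(d["ytr"], m.predict(d["Xtr"])) + 1e-9

    def test_json_round_trip(self, rng, tmp_path):
        X, y = _design(rng, n=30, p=4, noise=0.3)
        m = fit_regularized(X, y, "EN", folds=5, fold_seed=2)
        path = tmp_path / "m.json"
        m.save(path)
        back = FittedModel.load(path)
        assert back.algorithm == m.algorithm
        assert np.allclose(back.coef, m.coef)
        assert back.tuning["lambda"] == m.tuning["lambda"]
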