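"""The eight regression strategies for attractiveness modelling.

All models are fit on predictor-standardized training data (response left
on the rating scale, intercept fitted):

* OLS — all screened predictors in one least-squares model;
* SF / SB — forward / backward stepwise selection by AIC;
* PCR / PLSR — regression on principal / partial-least-squares components,
  the component count chosen by 10-fold cross-validated RMSE;
* RR / LASSO / EN — penalized least squares with penalty
  ``lambda * ((1 - alpha)/2 ||b||_2^2 + alpha ||b||_1)`` (glmnet
  convention; RR: alpha = 0, LASSO: alpha = 1, EN: alpha tuned over a
  grid), lambda chosen by 10-fold cross-validated RMSE on a log-spaced
  grid from lambda_max down four decades.

The same seeded fold partition is reused across all tuned methods so that
model comparisons are paired.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

__all__ = [
    "METHODS",
    "StandardizationParams",
    "FittedModel",
    "standardize",
    "fit_ols",
    "fit_stepwise",
    "fit_pcr",
    "fit_plsr",
    "fit_regularized",
    "fit_method",
    "fit_all",
    "penalized_fit",
    "rank_predictors",
]

METHODS = ("OLS", "SF", "SB", "PCR", "PLSR", "RR", "LASSO", "EN")

N_LAMBDAS = 50
LAMBDA_MIN_RATIO = 1e-4
EN_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


# ---------------------------------------------------------------------------
# standardization

@dataclass
class StandardizationParams:
    """Per-feature mean and SD estimated on the training faces."""

    mean: pd.Series
    sd: pd.Series
    ddof: int = 1

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Transform any table with the *training* parameters."""
        missing = set(self.mean.index) - set(table.columns)
        if missing:
            raise ValueError(f"table lacks standardized columns: {sorted(missing)}")
        return (table[self.mean.index] - self.mean) / self.sd


def standardize(
    train: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Scale training columns to mean 0, SD 1 (sample SD by default;
    ``ddof=0`` for the population convention)."""
    mean = train.mean()
    sd = train.std(ddof=ddof)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-SD columns cannot be standardized: {list(zero.index)}")
    params = StandardizationParams(mean, sd, ddof)
    return params.apply(train), params


# ---------------------------------------------------------------------------
# fitted-model container

@dataclass
class FittedModel:
    """One fitted regression: coefficients on standardized predictors."""

    algorithm: str
    intercept: float
    coef: pd.Series  # one entry per screened feature; exact zeros = unselected
    tuning: dict = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    fold_seed: int | None = None
    details: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Predict mean attractiveness; X must already be standardized with
        the training parameters."""
        return X[self.coef.index] @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "intercept": float(self.intercept),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "tuning": self.tuning,
            "selected": list(self.selected),
            "fold_seed": self.fold_seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            d["algorithm"],
            d["intercept"],
            pd.Series(d["coef"]),
            d.get("tuning", {}),
            d.get("selected", []),
            d.get("fold_seed"),
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_xy(X: pd.DataFrame, y: pd.Series):
    X, y = X.align(y, join="inner", axis=0)
    return X, X.to_numpy(dtype=float), y.to_numpy(dtype=float)


def make_folds(n: int, folds: int, fold_seed: int):
    """The shared seeded 10-fold partition used by every tuned method."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    return list(kf.split(np.arange(n)))


# ---------------------------------------------------------------------------
# OLS and stepwise

def _lstsq_fit(x: np.ndarray, y: np.ndarray):
    """Least squares with intercept; minimum-norm solution if rank-deficient."""
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient design: minimum-norm least-squares solution used",
            stacklevel=3,
        )
    resid = y - design @ beta
    return beta[0], beta[1:], float(resid @ resid)


def fit_ols(X: pd.DataFrame, y: pd.Series) -> FittedModel:
    """Ordinary least squares on all screened predictors."""
    X, x, yv = _as_xy(X, y)
    if len(yv) < 2:
        raise ValueError("need at least 2 faces")
    b0, b, rss = _lstsq_fit(x, yv)
    coef = pd.Series(b, index=X.columns)
    return FittedModel(
        "OLS", b0, coef, selected=list(X.columns), details={"rss": rss}
    )


def _aic(rss: float, n: int, p: int) -> float:
    """Gaussian-likelihood AIC up to an additive constant:
    n ln(RSS/n) + 2 (p + 2) (p slopes + intercept + error variance)."""
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * (p + 2)


def fit_stepwise(X: pd.DataFrame, y: pd.Series, direction: str = "forward") -> FittedModel:
    """Greedy stepwise selection by AIC.

    Forward starts from the intercept-only model and adds the single
    predictor lowering AIC the most; backward starts from the full model
    and removes; both stop when no move lowers AIC. AIC ties break by
    registry (column) order.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    X, x, yv = _as_xy(X, y)
    n = len(yv)
    if n < 2:
        raise ValueError("need at least 2 faces")
    cols = list(X.columns)

    def rss_of(subset: list[str]) -> float:
        if not subset:
            return float(((yv - yv.mean()) ** 2).sum())
        idx = [cols.index(c) for c in subset]
        return _lstsq_fit(x[:, idx], yv)[2]

    current = [] if direction == "forward" else list(cols)
    cur_aic = _aic(rss_of(current), n, len(current))
    trace = [{"step": 0, "move": None, "aic": cur_aic, "size": len(current)}]
    step = 0
    while True:
        candidates = (
            [c for c in cols if c not in current]
            if direction == "forward"
            else list(current)
        )
        if not candidates:
            break
        best_move, best_aic = None, cur_aic
        for c in candidates:  # registry order => deterministic tie-break
            subset = current + [c] if direction == "forward" else [v for v in current if v != c]
            a = _aic(rss_of(subset), n, len(subset))
            if a < best_aic - 1e-12:
                best_move, best_aic = c, a
        if best_move is None:
            break
        step += 1
        if direction == "forward":
            current = current + [best_move]
        else:
            current = [v for v in current if v != best_move]
        cur_aic = best_aic
        trace.append({"step": step, "move": best_move, "aic": cur_aic, "size": len(current)})

    selected = [c for c in cols if c in current]
    coef = pd.Series(0.0, index=cols)
    if selected:
        idx = [cols.index(c) for c in selected]
        b0, b, _ = _lstsq_fit(x[:, idx], yv)
        coef[selected] = b
    else:
        b0 = float(yv.mean())
    algo = "SF" if direction == "forward" else "SB"
    return FittedModel(
        algo, b0, coef, tuning={"aic": cur_aic}, selected=selected,
        details={"trace": trace},
    )


# ---------------------------------------------------------------------------
# dimension reduction

def _pcr_coef_path(xc: np.ndarray, yc: np.ndarray, kmax: int) -> np.ndarray:
    """Coefficients of PCR with 1..kmax components, shape (p, kmax)."""
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pos = s > s[0] * 1e-12 if len(s) else s > 0
    gamma = np.zeros_like(s)
    gamma[pos] = (u.T @ yc)[pos] / s[pos]
    contrib = vt.T * gamma  # (p, r): v_i * gamma_i
    path = np.cumsum(contrib, axis=1)
    if path.shape[1] < kmax:
        pad = np.repeat(path[:, -1:], kmax - path.shape[1], axis=1)
        path = np.hstack([path, pad])
    return path[:, :kmax]


def fit_pcr(X: pd.DataFrame, y: pd.Series, folds: int = 10, fold_seed: int = 0,
            k_grid=None) -> FittedModel:
    """Principal component regression; component count by CV RMSE."""
    X, x, yv = _as_xy(X, y)
    n, p = x.shape
    if n < folds:
        raise ValueError("need at least as many faces as folds")
    kmax = min(p, n - 1)
    ks = list(k_grid) if k_grid is not None else list(range(1, kmax + 1))
    if not ks:
        raise ValueError("empty component grid")
    splits = make_folds(n, folds, fold_seed)
    sse = np.zeros(len(ks))
    cnt = 0
    for tr, va in splits:
        xm, ym = x[tr].mean(axis=0), yv[tr].mean()
        path = _pcr_coef_path(x[tr] - xm, yv[tr] - ym, max(ks))
        pred = (x[va] - xm) @ path[:, [k - 1 for k in ks]] + ym
        sse += ((pred - yv[va][:, None]) ** 2).sum(axis=0)
        cnt += len(va)
    cv_rmse = np.sqrt(sse / cnt)
    k = ks[int(np.argmin(cv_rmse))]
    xm, ym = x.mean(axis=0), yv.mean()
    xc = x - xm
    path = _pcr_coef_path(xc, yv - ym, k)
    b = path[:, k - 1]
    s2 = np.linalg.svd(xc, compute_uv=False) ** 2
    coef = pd.Series(b, index=X.columns)
    return FittedModel(
        "PCR", float(ym - xm @ b), coef,
        tuning={"n_components": int(k), "cv_rmse": dict(zip(map(int, ks), map(float, cv_rmse)))},
        selected=list(X.columns), fold_seed=fold_seed,
        details={"explained_x_variance": float(s2[:k].sum() / s2.sum())},
    )


def fit_plsr(X: pd.DataFrame, y: pd.Series, folds: int = 10, fold_seed: int = 0,
             k_grid=None) -> FittedModel:
    """Partial least squares regression (NIPALS); latent-component count
    by CV RMSE; coefficients reported in the original feature space."""
    X, x, yv = _as_xy(X, y)
    n, p = x.shape
    if n < folds:
        raise ValueError("need at least as many faces as folds")
    splits = make_folds(n, folds, fold_seed)
    kmax = min(p, min(len(tr) for tr, _ in splits))
    ks = list(k_grid) if k_grid is not None else list(range(1, kmax + 1))
    if not ks:
        raise ValueError("empty component grid")
    sse = np.zeros(len(ks))
    cnt = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NIPALS convergence chatter at large k
        for tr, va in splits:
            for j, k in enumerate(ks):
                pls = PLSRegression(n_components=k, scale=False).fit(x[tr], yv[tr])
                pred = pls.predict(x[va]).ravel()
                sse[j] += ((pred - yv[va]) ** 2).sum()
            cnt += len(va)
        cv_rmse = np.sqrt(sse / cnt)
        k = ks[int(np.argmin(cv_rmse))]
        pls = PLSRegression(n_components=k, scale=False).fit(x, yv)
    b = pls.coef_.reshape(-1) if pls.coef_.shape[0] == 1 else pls.coef_.ravel()
    if b.shape[0] != p:
        b = pls.coef_.T.ravel()
    xm, ym = x.mean(axis=0), yv.mean()
    coef = pd.Series(b, index=X.columns)
    return FittedModel(
        "PLSR", float(ym - xm @ b), coef,
        tuning={"n_components": int(k), "cv_rmse": dict(zip(map(int, ks), map(float, cv_rmse)))},
        selected=list(X.columns), fold_seed=fold_seed,
    )


# ---------------------------------------------------------------------------
# regularisation

def _ridge_path(xc: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Closed-form ridge for objective 1/(2n)||yc - Xc b||^2 + lam/2 ||b||^2,
    all lambdas at once; shape (p, L)."""
    n = len(yc)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    uty = u.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = s[:, None] / (s[:, None] ** 2 + n * lams[None, :])
    shrink = np.nan_to_num(shrink)
    return vt.T @ (shrink * uty[:, None])


def penalized_fit(
    X: pd.DataFrame, y: pd.Series, lam: float, alpha: float
) -> FittedModel:
    """Elastic-net fit at a fixed (lambda, alpha); closed-form ridge when
    alpha = 0 (minimum-norm least squares at lambda = 0)."""
    X, x, yv = _as_xy(X, y)
    n = len(yv)
    xm, ym = x.mean(axis=0), yv.mean()
    if alpha == 0.0:
        if lam == 0.0:
            b0, b, _ = _lstsq_fit(x, yv)
            coef = pd.Series(b, index=X.columns)
            return FittedModel("RR", b0, coef, tuning={"lambda": 0.0, "alpha": 0.0},
                               selected=list(X.columns))
        b = _ridge_path(x - xm, yv - ym, np.array([lam]))[:, 0]
    else:
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True,
            max_iter=100000, tol=1e-8,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, yv)
        b = est.coef_
    coef = pd.Series(b, index=X.columns)
    selected = list(coef.index[coef != 0]) if alpha > 0 else list(X.columns)
    return FittedModel(
        "EN", float(ym - xm @ b), coef,
        tuning={"lambda": float(lam), "alpha": float(alpha)}, selected=selected,
    )


def lambda_max(x: np.ndarray, yv: np.ndarray, alpha: float) -> float:
    """Smallest penalty that zeroes every coefficient (KKT bound):
    max_j |x_j^T (y - ybar)| / (n max(alpha, 0.001))."""
    n = len(yv)
    return float(
        np.max(np.abs(x.T @ (yv - yv.mean()))) / (n * max(alpha, 0.001))
    )


def _lambda_grid(x, yv, alpha) -> np.ndarray:
    lmax = lambda_max(x, yv, alpha)
    return np.geomspace(lmax, lmax * LAMBDA_MIN_RATIO, N_LAMBDAS)  # descending


def _cv_rmse_en(x, yv, alpha, lams, splits) -> np.ndarray:
    sse = np.zeros(len(lams))
    cnt = 0
    for tr, va in splits:
        xm, ym = x[tr].mean(axis=0), yv[tr].mean()
        xc, yc = x[tr] - xm, yv[tr] - ym
        if alpha == 0.0:
            coefs = _ridge_path(xc, yc, lams)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(xc, yc, l1_ratio=alpha, alphas=lams)
        pred = (x[va] - xm) @ coefs + ym
        sse += ((pred - yv[va][:, None]) ** 2).sum(axis=0)
        cnt += len(va)
    return np.sqrt(sse / cnt)


def fit_regularized(
    X: pd.DataFrame,
    y: pd.Series,
    method: str = "EN",
    folds: int = 10,
    fold_seed: int = 0,
    one_se: bool = False,
) -> FittedModel:
    """Ridge / LASSO / elastic-net with 10-fold CV tuning.

    lambda is tuned on a 50-point log grid from lambda_max down 4 decades;
    EN additionally tunes alpha over {0, 0.1, ..., 1}. Selection minimizes
    the mean CV RMSE (the 1-SE rule is available via ``one_se``); lambda
    ties resolve to the stronger penalty.
    """
    if method not in ("RR", "LASSO", "EN"):
        raise ValueError("method must be RR, LASSO or EN")
    X, x, yv = _as_xy(X, y)
    n = x.shape[0]
    if n < folds:
        raise ValueError("need at least as many faces as folds")
    if np.var(yv) == 0:
        raise ValueError("response has zero variance")
    splits = make_folds(n, folds, fold_seed)
    alphas = {"RR": (0.0,), "LASSO": (1.0,)}.get(method, EN_ALPHA_GRID)
    best = None
    cv_tables = {}
    for alpha in alphas:
        lams = _lambda_grid(x, yv, alpha)
        rmse = _cv_rmse_en(x, yv, alpha, lams, splits)
        cv_tables[float(alpha)] = {"lambda": lams.tolist(), "cv_rmse": rmse.tolist()}
        i = int(np.argmin(rmse))  # grid descending => ties pick larger lambda
        if one_se:
            thresh = rmse[i] + rmse[i] / np.sqrt(2 * folds)
            i = int(np.argmax(rmse <= thresh))
        if best is None or rmse[i] < best[0] - 1e-15:
            best = (float(rmse[i]), float(alpha), float(lams[i]))
    cv_rmse, alpha, lam = best
    fitted = penalized_fit(X, pd.Series(yv, index=X.index), lam, alpha)
    fitted.algorithm = method
    fitted.fold_seed = fold_seed
    fitted.tuning = {"lambda": lam, "alpha": alpha, "cv_rmse": cv_rmse,
                     "one_se": one_se}
    fitted.details = {"cv_tables": cv_tables}
    return fitted


# ---------------------------------------------------------------------------
# dispatch and ranking

def fit_method(method: str, X: pd.DataFrame, y: pd.Series,
               folds: int = 10, fold_seed: int = 0) -> FittedModel:
    """Fit one of the eight strategies by name."""
    if method == "OLS":
        return fit_ols(X, y)
    if method == "SF":
        return fit_stepwise(X, y, "forward")
    if method == "SB":
        return fit_stepwise(X, y, "backward")
    if method == "PCR":
        return fit_pcr(X, y, folds, fold_seed)
    if method == "PLSR":
        return fit_plsr(X, y, folds, fold_seed)
    if method in ("RR", "LASSO", "EN"):
        return fit_regularized(X, y, method, folds, fold_seed)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def fit_all(X: pd.DataFrame, y: pd.Series, folds: int = 10,
            fold_seed: int = 0) -> dict[str, FittedModel]:
    """Fit all eight strategies on the same data and fold partition."""
    return {m: fit_method(m, X, y, folds, fold_seed) for m in METHODS}


def rank_predictors(model: FittedModel) -> pd.DataFrame:
    """Rank features by |standardized coefficient|, descending.

    Unselected features (stepwise / LASSO / EN zeros) get rank 0; selected
    features are ranked 1 = most important.
    """
    coef = model.coef
    in_model = coef.index.isin(model.selected) & (coef.to_numpy() != 0)
    order = np.argsort(-np.abs(coef.to_numpy()), kind="stable")
    rank = pd.Series(0, index=coef.index, dtype=int)
    r = 1
    for i in order:
        if in_model[i]:
            rank.iloc[i] = r
            r += 1
    return pd.DataFrame({"coefficient": coef, "rank": rank})
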