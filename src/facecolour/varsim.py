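"""The variable-count overfitting simulation.

For each candidate predictor count N, sample N features at random from
the screened set, fit each method on the training faces and score both
panels; repeat (30 iterations by default) and aggregate mean and SD of
the RMSEs. At N = 1 regularisation is not applied — both arms reduce to
simple (univariate) regression, so that point shows the spread of the
conventional univariate approach. The same sampled subset feeds every
method within one iteration (paired comparison), and the elastic net is
re-tuned by 10-fold CV inside every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import rmse
from .models import fit_ols, fit_regularized

__all__ = ["VarCountResult", "run_varcount"]

DEFAULT_N_GRID = (1, 3, 6, 10, 15, 21)


@dataclass
class VarCountResult:
    """Aggregated RMSE curves of the N-sweep."""

    summary: pd.DataFrame  # columns: N, method, mean/sd of train/test rmse
    per_iteration: pd.DataFrame
    seed: int
    iterations: int

    def curve(self, method: str, which: str = "test") -> pd.Series:
        sub = self.summary[self.summary["method"] == method]
        return sub.set_index("N")[f"mean_{which}_rmse"]

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _fit_arm(method, Xs, y, folds, fold_seed):
    if Xs.shape[1] == 1 or method == "OLS":
        return fit_ols(Xs, y)  # N = 1: plain simple regression, both arms
    return fit_regularized(Xs, y, method, folds=folds, fold_seed=fold_seed)


def run_varcount(
    train: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series],
    relevant: list[str] | None = None,
    n_grid=DEFAULT_N_GRID,
    methods=("EN", "OLS"),
    iterations: int = 30,
    seed: int = 0,
    folds: int = 10,
    nested: bool = False,
) -> VarCountResult:
    """Sweep the number of randomly chosen predictors N.

    ``train`` / ``test`` are (standardized features, mean scores) on the
    training standardization. Subsets are drawn without replacement,
    independently per (N, iteration); ``nested=True`` grows each
    iteration's subset incrementally across the N grid instead (used for
    monotonicity checks only).
    """
    Xtr, ytr = train
    Xte, yte = test
    pool = list(relevant) if relevant is not None else list(Xtr.columns)
    n_grid = sorted(int(n) for n in n_grid)
    if not pool:
        raise ValueError("empty relevant-feature pool")
    if n_grid[0] < 1 or n_grid[-1] > len(pool):
        raise ValueError(
            f"N grid must lie within [1, {len(pool)}], got {n_grid}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iterations):
        fold_seed = int(rng.integers(2**31 - 1))
        if nested:
            perm = list(rng.permutation(pool))
        for N in n_grid:
            if nested:
                subset = perm[:N]
            else:
                subset = list(rng.choice(pool, size=N, replace=False))
            for method in methods:
                model = _fit_arm(method, Xtr[subset], ytr, folds, fold_seed)
                rows.append(
                    {
                        "iteration": it,
                        "N": N,
                        "method": method,
                        "train_rmse": rmse(ytr, model.predict(Xtr[subset])),
                        "test_rmse": rmse(yte, model.predict(Xte[subset])),
                    }
                )
    per_it = pd.DataFrame(rows)
    summary = (
        per_it.groupby(["N", "method"], as_index=False)
        .agg(
            mean_train_rmse=("train_rmse", "mean"),
            sd_train_rmse=("train_rmse", lambda s: s.std(ddof=0)),
            mean_test_rmse=("test_rmse", "mean"),
            sd_test_rmse=("test_rmse", lambda s: s.std(ddof=0)),
        )
        .sort_values(["method", "N"], ignore_index=True)
    )
    return VarCountResult(summary, per_it, seed=seed, iterations=iterations)
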