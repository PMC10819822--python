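"""Model comparison: accuracy, goodness of fit, rankings, clustering.

Step 4 of the framework. Accuracy is RMSE in rating units; goodness of
fit R² is the *squared Pearson correlation* between observed and
predicted scores — by that definition R² is insensitive to calibration
(an affinely mis-scaled predictor still scores 1), so a conventional
coefficient of determination is also emitted for transparency but never
used in comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .models import FittedModel, rank_predictors

__all__ = [
    "rmse",
    "r_squared",
    "coefficient_of_determination",
    "EvaluationReport",
    "compare_models",
    "cluster_predictors",
]


def rmse(observed, predicted) -> float:
    """Root mean squared error, in rating units."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted.

    NaN (with a warning) when either vector is constant.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("constant vector: R^2 undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def coefficient_of_determination(observed, predicted) -> float:
    """Conventional 1 - SSE/SST (can be negative out of sample)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


@dataclass
class EvaluationReport:
    """Per-model accuracy table plus the cross-model predictor ranking."""

    table: pd.DataFrame  # index: algorithm
    rankings: pd.DataFrame  # index: feature, columns: algorithm, values: rank (0 = unselected)
    predictions: dict  # algorithm -> {"train": Series, "test": Series}

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "model_comparison.csv")
        self.rankings.to_csv(outdir / "predictor_rankings.csv")


def compare_models(
    models: "dict[str, FittedModel] | list[FittedModel]",
    train: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series] | None = None,
) -> EvaluationReport:
    """Fill the accuracy/fit table for a set of fitted models.

    ``train`` and ``test`` are (standardized features, mean scores); the
    test features must have been standardized with the *training*
    parameters. R² columns are reported in percent.
    """
    if not isinstance(models, dict):
        models = {m.algorithm: m for m in models}
    Xtr, ytr = train
    rows, rank_cols, preds = {}, {}, {}
    for name, model in models.items():
        p_tr = model.predict(Xtr)
        row = {
            "train_rmse": rmse(ytr, p_tr),
            "train_r2_pct": 100.0 * r_squared(ytr, p_tr),
            "train_r2_determination_pct": 100.0 * coefficient_of_determination(ytr, p_tr),
        }
        preds[name] = {"train": p_tr}
        if test is not None:
            Xte, yte = test
            p_te = model.predict(Xte)
            row.update(
                test_rmse=rmse(yte, p_te),
                test_r2_pct=100.0 * r_squared(yte, p_te),
                test_r2_determination_pct=100.0 * coefficient_of_determination(yte, p_te),
            )
            preds[name]["test"] = p_te
        row["n_selected"] = model.n_selected
        rows[name] = row
        rank_cols[name] = rank_predictors(model)["rank"]
    table = pd.DataFrame(rows).T
    table.index.name = "algorithm"
    table["n_selected"] = table["n_selected"].astype(int)
    rankings = pd.DataFrame(rank_cols)
    rankings.index.name = "feature"
    return EvaluationReport(table, rankings, preds)


def cluster_predictors(
    features: pd.DataFrame,
    cut_distance: float = 0.5,
):
    """Group correlated predictors by hierarchical clustering.

    Distance 1 - |r| (sign-blind) with average linkage. Constant columns
    are dropped with a warning. Returns a dict with the scipy linkage
    matrix, the dendrogram leaf order, and flat groups at ``cut_distance``.
    """
    sd = features.std(ddof=0)
    const = list(sd.index[sd == 0])
    if const:
        warnings.warn(f"constant predictors dropped from clustering: {const}",
                      stacklevel=2)
        features = features.drop(columns=const)
    names = list(features.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 non-constant predictors")
    corr = np.corrcoef(features.to_numpy(dtype=float), rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    flat = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    groups: dict[int, list[str]] = {}
    for name, g in zip(names, flat):
        groups.setdefault(int(g), []).append(name)
    # order groups by first appearance along the dendrogram
    ordered_groups = []
    seen = set()
    for i in leaves:
        g = int(flat[i])
        if g not in seen:
            seen.add(g)
            ordered_groups.append(groups[g])
    return {
        "linkage": link,
        "leaf_order": [names[i] for i in leaves],
        "groups": ordered_groups,
        "dropped": const,
    }
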