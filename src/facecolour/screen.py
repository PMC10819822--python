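"""Observer-consistency diagnostics and correlation screening.

Steps 1–2 of the framework: check that the rating panels are internally
consistent (Cronbach's alpha over observers, cross-site correlation of the
overlap faces), average ratings into one score per face, and keep the
colour features whose two-tailed Pearson correlation with the score is
significant at the chosen level (no multiple-testing correction by
default, matching the p < 0.05 keep rule; Benjamini–Hochberg is available
behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsPanel",
    "ScreeningReport",
    "mean_ratings",
    "cronbach_alpha",
    "pearson_screen",
    "cross_site_consistency",
    "fisher_ci",
]

RATING_MIN, RATING_MAX = 1, 7


@dataclass
class RatingsPanel:
    """An observer × face matrix of integer Likert ratings with a site tag."""

    ratings: pd.DataFrame  # index: observer_id, columns: face_id
    site: str = "train"

    def __post_init__(self) -> None:
        df = self.ratings
        if df.isna().any().any():
            raise ValueError("ratings panel has missing cells (imputation is out of scope)")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("ratings must be integers")
            self.ratings = df.astype(int)
            vals = self.ratings.to_numpy()
        if vals.min() < RATING_MIN or vals.max() > RATING_MAX:
            raise ValueError(f"ratings must lie in [{RATING_MIN}, {RATING_MAX}]")

    @property
    def n_observers(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_faces(self) -> int:
        return self.ratings.shape[1]

    def to_long_csv(self, path) -> None:
        long = self.ratings.stack().rename("rating").reset_index()
        long.columns = ["observer_id", "face_id", "rating"]
        long["site"] = self.site
        long.to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path, site: str | None = None) -> "RatingsPanel":
        long = pd.read_csv(path)
        if site is None:
            site = str(long["site"].iloc[0]) if "site" in long else "train"
        wide = long.pivot(index="observer_id", columns="face_id", values="rating")
        return cls(wide, site=site)


def mean_ratings(panel: RatingsPanel) -> pd.Series:
    """Average ratings over observers: one attractiveness score per face."""
    scores = panel.ratings.mean(axis=0)
    scores.index.name = "face_id"
    return scores


def cronbach_alpha(panel: "RatingsPanel | pd.DataFrame", ci: float = 0.95):
    """Cronbach's alpha with observers as items and faces as cases.

    alpha = k/(k-1) * (1 - sum_o var_o / var_total), sample variances over
    faces; the confidence interval is the Feldt F-distribution interval.
    Accepts a :class:`RatingsPanel` or a raw observer × face DataFrame.

    Returns ``(alpha, (lo, hi))``; alpha is NaN (with a warning) when the
    total score has zero variance across faces.
    """
    ratings = panel.ratings if isinstance(panel, RatingsPanel) else panel
    k, n = ratings.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 observers and 2 faces")
    x = ratings.to_numpy(dtype=float)
    var_total = x.sum(axis=0).var(ddof=1)
    if var_total == 0:
        warnings.warn("total rating variance is zero; alpha undefined", stacklevel=2)
        return float("nan"), (float("nan"), float("nan"))
    item_vars = x.var(axis=1, ddof=1).sum()
    alpha = k / (k - 1.0) * (1.0 - item_vars / var_total)
    a = 1.0 - ci
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - a / 2.0, df1, df2)
    hi = 1.0 - (1.0 - alpha) * stats.f.ppf(a / 2.0, df1, df2)
    return float(alpha), (float(lo), float(hi))


@dataclass
class ScreeningReport:
    """Per-feature Pearson r, two-tailed p and the keep decision."""

    table: pd.DataFrame  # index: feature; columns: r, p, keep
    n_faces: int
    alpha_level: float

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["keep"]])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path)


def pearson_screen(
    features: pd.DataFrame,
    scores: pd.Series,
    alpha_level: float = 0.05,
    fdr: bool = False,
) -> ScreeningReport:
    """Keep features significantly correlated with mean attractiveness.

    Two-tailed p from t = r sqrt((n-2)/(1-r^2)) on n-2 df. Constant
    features have undefined r and are excluded with a warning, never
    silently kept. ``fdr=True`` applies Benjamini–Hochberg to the p-values
    before the keep rule (off by default).
    """
    features, scores = features.align(scores, join="inner", axis=0)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 faces for screening")
    y = scores.to_numpy(dtype=float)
    x = features.to_numpy(dtype=float)
    xm = x - x.mean(axis=0)
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum(axis=0))
    sy = np.sqrt((ym**2).sum())
    if sy == 0:
        raise ValueError("scores are constant; screening undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm * ym[:, None]).sum(axis=0) / (sx * sy)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    const = sx == 0
    if const.any():
        warnings.warn(
            f"constant features excluded from screening: "
            f"{list(features.columns[const])}",
            stacklevel=2,
        )
    r = np.where(const, np.nan, r)
    p = np.where(const, np.nan, p)
    p_eff = p
    if fdr:
        p_eff = _bh_adjust(p)
    keep = np.where(np.isnan(p_eff), False, p_eff < alpha_level)
    table = pd.DataFrame(
        {"r": r, "p": p, "keep": keep.astype(bool)}, index=features.columns
    )
    if fdr:
        table["p_adj"] = p_eff
    return ScreeningReport(table, n_faces=n, alpha_level=alpha_level)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan, dtype=float)
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps)
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def fisher_ci(r: float, n: int, ci: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation:
    tanh(atanh(r) ± z_{1-a/2} / sqrt(n - 3))."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher interval")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + ci / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def cross_site_consistency(
    scores_a: pd.Series, scores_b: pd.Series, ci: float = 0.95
):
    """Pearson correlation between the two sites' mean scores on the same
    faces, with a Fisher-z confidence interval.

    Returns ``(r, (lo, hi), degenerate)``; ``degenerate`` flags |r| = 1,
    where the interval collapses.
    """
    a, b = scores_a.align(scores_b, join="inner")
    n = len(a)
    if n < 4:
        raise ValueError("need at least 4 shared faces")
    r = float(np.corrcoef(a.to_numpy(float), b.to_numpy(float))[0, 1])
    degenerate = bool(np.isclose(abs(r), 1.0))
    if degenerate:
        warnings.warn("|r| = 1: Fisher interval degenerate", stacklevel=2)
        return r, (r, r), True
    return r, fisher_ci(r, n, ci), False
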