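"""Rating diagnostics and correlation screening."""

import numpy as np
import pandas as pd
import pytest

from facecolour.screen import (
    RatingsPanel,
    cronbach_alpha,
    cross_site_consistency,
    fisher_ci,
    mean_ratings,
    pearson_screen,
)


def _panel(arr, site="train"):
    arr = np.asarray(arr)
    return RatingsPanel(
        pd.DataFrame(
            arr,
            index=[f"o{i}" for i in range(arr.shape[0])],
            columns=[f"f{j}" for j in range(arr.shape[1])],
        ),
        site=site,
    )


class TestRatingsPanel:
    def test_rejects_out_of_scale(self):
        with pytest.raises(ValueError, match=r"\[1, 7\]"):
            _panel([[1, 8], [2, 3]])

    def test_rejects_missing_cells(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            RatingsPanel(df)

    def test_long_csv_round_trip(self, tmp_path):
        p = _panel([[1, 2, 3], [4, 5, 6]], site="test")
        path = tmp_path / "r.csv"
        p.to_long_csv(path)
        q = RatingsPanel.from_long_csv(path)
        assert q.site == "test"
        assert q.ratings.sort_index(axis=1).equals(p.ratings.sort_index(axis=1))


class TestMeanRatings:
    def test_unanimous_and_simple_average(self):
        p = _panel([[5, 4], [5, 6]])
        s = mean_ratings(p)
        assert s["f0"] == 5.0 and s["f1"] == 5.0

    def test_noise_free_scores_equal_latent_prediction(self):
        from facecolour.synth import generate_study

        study = generate_study(
            seed=3, observer_bias_sd=0.0, rating_noise_sd=0.0, face_noise_sd=0.0
        )
        scores = mean_ratings(study.train_panel)
        expected = np.clip(np.round(4.0 + study.latent), 1, 7)
        assert np.allclose(scores, expected.loc[scores.index])


class TestCronbachAlpha:
    def test_identical_observers_give_alpha_one(self):
        p = _panel(np.tile([1, 4, 7, 3, 5], (4, 1)))
        alpha, (lo, hi) = cronbach_alpha(p)
        assert alpha == pytest.approx(1.0)
        assert lo == pytest.approx(1.0)

    def test_spearman_brown_identity_for_two_observers(self):
        # two observers with sample correlation exactly 0.8 and equal
        # variances: alpha = 2 r / (1 + r) = 8/9
        z1 = np.array([1.0, -1.0, 0.5, -0.5, 0.0, 0.3, -0.3, 0.8, -0.8, 0.0])
        z1 = (z1 - z1.mean()) / z1.std(ddof=1)
        v = np.arange(10, dtype=float)
        v -= v.mean()
        z2 = v - (v @ z1) / (z1 @ z1) * z1
        z2 /= z2.std(ddof=1)
        df = pd.DataFrame(np.vstack([z1, 0.8 * z1 + 0.6 * z2]) + 4)
        alpha, _ = cronbach_alpha(df)
        assert alpha == pytest.approx(2 * 0.8 / 1.8, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        arr = rng.integers(1, 8, size=(10, 30))
        p = _panel(arr)
        alpha, (lo, hi) = cronbach_alpha(p)
        a_ref, ci_ref = pingouin.cronbach_alpha(
            data=pd.DataFrame(arr.T)
        )
        assert alpha == pytest.approx(a_ref, abs=1e-10)
        assert lo == pytest.approx(ci_ref[0], abs=0.005)
        assert hi == pytest.approx(ci_ref[1], abs=0.005)

    def test_independent_ratings_give_alpha_near_zero(self, rng):
        alphas = []
        for _ in range(20):
            arr = rng.integers(1, 8, size=(20, 200))
            alphas.append(cronbach_alpha(_panel(arr))[0])
        assert abs(np.mean(alphas)) < 0.05

    def test_invariant_to_constant_shift(self, rng):
        arr = rng.integers(2, 6, size=(8, 25))
        a1, _ = cronbach_alpha(_panel(arr))
        a2, _ = cronbach_alpha(_panel(arr + 1))
        assert a1 == pytest.approx(a2)

    def test_zero_variance_flagged(self):
        p = _panel(np.full((3, 5), 4))
        with pytest.warns(UserWarning, match="zero"):
            alpha, _ = cronbach_alpha(p)
        assert np.isnan(alpha)


def _vector_with_exact_r(scores: np.ndarray, r: float, rng) -> np.ndarray:
    """Construct a feature whose sample correlation with scores is
    exactly r (Gram-Schmidt construction)."""
    y = (scores - scores.mean()) / scores.std(ddof=0)
    w = rng.standard_normal(len(scores))
    w -= w.mean()
    w -= (w @ y) / (y @ y) * y
    w /= w.std(ddof=0)
    return r * y + np.sqrt(1 - r * r) * w


class TestPearsonScreen:
    def test_perfectly_correlated_feature_kept(self, rng):
        scores = pd.Series(rng.normal(4, 1, 30))
        feats = pd.DataFrame({"x": scores * 2 + 1})
        rep = pearson_screen(feats, scores)
        assert rep.table.loc["x", "r"] == pytest.approx(1.0)
        assert rep.table.loc["x", "keep"]

    def test_keep_threshold_matches_critical_r_at_n40(self, rng):
        scores = pd.Series(rng.normal(4, 1, 40))
        feats = pd.DataFrame(
            {
                "just_above": _vector_with_exact_r(scores.to_numpy(), 0.35, rng),
                "just_below": _vector_with_exact_r(scores.to_numpy(), 0.30, rng),
            },
            index=scores.index,
        )
        rep = pearson_screen(feats, scores)
        assert rep.table.loc["just_above", "keep"]
        assert not rep.table.loc["just_below", "keep"]

    def test_p_values_match_scipy(self, rng):
        from scipy import stats

        scores = pd.Series(rng.normal(4, 1, 25))
        feats = pd.DataFrame(rng.normal(size=(25, 6)), index=scores.index)
        rep = pearson_screen(feats, scores)
        for c in feats.columns:
            r_ref, p_ref = stats.pearsonr(feats[c], scores)
            assert rep.table.loc[c, "r"] == pytest.approx(r_ref)
            assert rep.table.loc[c, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_feature_excluded_with_warning(self, rng):
        scores = pd.Series(rng.normal(4, 1, 20))
        feats = pd.DataFrame(
            {"flat": np.ones(20), "ok": rng.normal(size=20)}, index=scores.index
        )
        with pytest.warns(UserWarning, match="flat"):
            rep = pearson_screen(feats, scores)
        assert not rep.table.loc["flat", "keep"]
        assert np.isnan(rep.table.loc["flat", "r"])

    def test_affine_rescaling_invariance(self, rng):
        scores = pd.Series(rng.normal(4, 1, 30))
        x = rng.normal(size=30)
        r1 = pearson_screen(pd.DataFrame({"x": x}, index=scores.index), scores)
        r2 = pearson_screen(
            pd.DataFrame({"x": -3.0 * x + 7.0}, index=scores.index), scores
        )
        assert r1.table.loc["x", "p"] == pytest.approx(r2.table.loc["x", "p"])
        assert r1.table.loc["x", "r"] == pytest.approx(-r2.table.loc["x", "r"])

    def test_keep_monotone_in_abs_r(self, rng):
        scores = pd.Series(rng.normal(4, 1, 40))
        rs = [0.1, 0.25, 0.32, 0.5, 0.8]
        feats = pd.DataFrame(
            {f"r{r}": _vector_with_exact_r(scores.to_numpy(), r, rng) for r in rs},
            index=scores.index,
        )
        rep = pearson_screen(feats, scores)
        kept_flags = [rep.table.loc[f"r{r}", "keep"] for r in rs]
        assert kept_flags == sorted(kept_flags)  # once kept, stays kept

    def test_bh_option_is_more_conservative(self, rng):
        scores = pd.Series(rng.normal(4, 1, 40))
        feats = pd.DataFrame(rng.normal(size=(40, 30)), index=scores.index)
        plain = pearson_screen(feats, scores)
        fdr = pearson_screen(feats, scores, fdr=True)
        assert set(fdr.kept) <= set(plain.kept)


class TestCrossSiteConsistency:
    def test_printed_interval_for_r94_n40(self):
        lo, hi = fisher_ci(0.94, 40)
        assert round(lo, 2) == 0.89
        assert round(hi, 2) == 0.97

    def test_identical_vectors_degenerate(self, rng):
        s = pd.Series(rng.normal(4, 1, 10))
        with pytest.warns(UserWarning, match="degenerate"):
            r, ci, degen = cross_site_consistency(s, s)
        assert r == pytest.approx(1.0)
        assert degen

    def test_independent_vectors_near_zero(self, rng):
        a = pd.Series(rng.normal(size=2000))
        b = pd.Series(rng.normal(size=2000))
        r, ci, _ = cross_site_consistency(a, b)
        assert abs(r) < 0.08
        assert ci[0] < 0 < ci[1]

    def test_too_few_faces_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cross_site_consistency(s, s + 1)
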