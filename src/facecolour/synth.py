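"""Synthetic faces, feature tables and observer rating panels.

Two generator levels:

* **image-level** — geometric face templates (ellipses/rectangles on a
  256 px canvas) filled with per-face region colours drawn in CIELAB plus
  i.i.d. per-pixel noise, written out as sRGB; exercises the extractor
  end-to-end.
* **table-level** — 65-feature tables drawn from a latent-factor model
  (shared lightness / redness / yellowness / hue / heterogeneity / contrast
  factors) so that within-block correlations are high and cross-block
  correlations moderate, as in real facial colour data; fast enough for
  regression tests.

Ratings follow a round-and-clamp Likert response model on a 1–7 scale:
observer o rates face f as ``clamp(round(m + b_o + s_f + d_f + eps_of),
1, 7)`` with a sparse linear colour score ``s_f = sum_j beta_j z_j(f)``
over the true support, a colour-independent face appeal ``d_f`` shared by
all observers, observer bias ``b_o`` and trial noise ``eps_of``.

The defaults emulate the study design this package analyses: a training
panel of 22 observers × 40 faces and a testing panel of 51 observers ×
(60 new + 40 overlap) faces, with a sparse truth of 11 features.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colourspace import lab_to_srgb
from .features import COORDS, FEATURE_NAMES, extract_table
from .regions import LABELS, RegionMaskSet
from .screen import RatingsPanel

__all__ = [
    "SynthConfig",
    "FacePanel",
    "FactorModel",
    "SynthStudy",
    "build_label_template",
    "generate_face_panel",
    "generate_feature_table",
    "generate_ratings",
    "generate_study",
    "generate_image_study",
    "latent_scores",
]

# (mean Lab, SD Lab) per region: light East-Asian skin tones on mid-grey.
DEFAULT_PALETTE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "background": ((50.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    "forehead": ((62.0, 12.0, 16.0), (3.0, 2.0, 2.0)),
    "cheek": ((60.0, 14.0, 16.0), (3.0, 2.5, 2.0)),
    "nose": ((61.0, 13.0, 15.5), (3.0, 2.0, 2.0)),
    "chin": ((59.0, 13.0, 16.0), (3.0, 2.0, 2.0)),
    "periorbital": ((57.0, 13.0, 15.0), (3.0, 2.0, 2.0)),
    "other_skin": ((60.0, 13.0, 16.0), (3.0, 2.0, 2.0)),
    "lips": ((45.0, 25.0, 14.0), (4.0, 3.0, 2.0)),
    "brows": ((25.0, 6.0, 8.0), (4.0, 2.0, 2.0)),
    "eyes": ((22.0, 5.0, 6.0), (4.0, 1.5, 1.5)),
}

#: Default sparse truth: the strongest colour cues of attractiveness
#: (brow redness contrast, skin heterogeneity, local hue/lightness, mouth
#: contrast), with standardized effects in rating units per feature SD.
DEFAULT_SUPPORT: tuple[str, ...] = (
    "Brows_C_a*",
    "MCDM",
    "Nose_h_ab",
    "MCDM_Cheek",
    "Mouth_C_a*",
    "Chin_L*",
    "Forehead_h_ab",
    "Chin_h_ab",
    "Cheek_L*",
    "Nose_L*",
    "Mouth_C_h_ab",
)
DEFAULT_BETA: tuple[float, ...] = (
    -0.270, -0.253, 0.236, -0.218, -0.201, 0.183, 0.166, 0.149, 0.131, 0.114, -0.097
)

#: Signed loading of each latent factor on a common "skin quality" axis:
#: lighter, warmer-hued, more uniform skin with stronger mouth/brow
#: contrasts co-occurs across faces, so the factors driving attractiveness
#: are mutually correlated with the signs their effects imply.
DEFAULT_FACTOR_WEIGHTS: dict[str, float] = {
    "lightness": 0.55,
    "hue": 0.55,
    "heterogeneity": -0.55,
    "contrast_mouth": -0.55,
    "contrast_brows": -0.55,
    "redness": 0.15,
    "yellowness": 0.0,
    "contrast_eyes": 0.15,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study. All randomness flows from ``seed``."""

    n_faces_train: int = 40
    n_faces_test: int = 60
    n_observers_train: int = 22
    n_observers_test: int = 51
    n_overlap_faces: int = 40
    region_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    pixel_noise_sd_range: tuple[float, float] = (1.0, 3.0)
    true_support: tuple[str, ...] = DEFAULT_SUPPORT
    true_beta: tuple[float, ...] = DEFAULT_BETA
    observer_bias_sd: float = 0.5
    rating_noise_sd: float = 0.8
    face_noise_sd: float = 0.9  # colour-independent appeal, shared by observers
    rating_midpoint: float = 4.0
    seed: int = 0
    canvas: int = 256
    region_corr: float = 0.6  # shared variance fraction across skin regions
    factor_weights: dict | None = None  # None -> DEFAULT_FACTOR_WEIGHTS

    RATING_SCALE = (1, 7)

    def __post_init__(self) -> None:
        counts = (
            self.n_faces_train,
            self.n_faces_test,
            self.n_observers_train,
            self.n_observers_test,
            self.n_overlap_faces,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all panel counts must be positive")
        if self.n_overlap_faces > self.n_faces_train:
            raise ValueError("n_overlap_faces cannot exceed n_faces_train")
        if len(self.true_support) != len(self.true_beta):
            raise ValueError("true_support and true_beta lengths differ")
        if any(b != 0 for b in self.true_beta) and not self.true_support:
            raise ValueError("nonzero true_beta requires a non-empty true_support")
        unknown = set(self.true_support) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"true_support not in the 65-feature registry: {sorted(unknown)}")
        lo, hi = self.pixel_noise_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("pixel_noise_sd_range must be 0 <= lo <= hi")

    @property
    def n_faces(self) -> int:
        return self.n_faces_train + self.n_faces_test

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class FacePanel:
    """Synthetic images + masks + the parameters that generated them."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    face_ids: list[str]
    ground_truth: dict

    def mask_sets(self) -> list[RegionMaskSet]:
        return [RegionMaskSet(m) for m in self.masks]

    def save(self, outdir) -> None:
        from PIL import Image

        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        for fid, img, msk in zip(self.face_ids, self.images, self.masks):
            Image.fromarray(img).save(outdir / "images" / f"{fid}.png")
            Image.fromarray(msk).save(outdir / "masks" / f"{fid}.png")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def build_label_template(size: int = 256) -> np.ndarray:
    """Fixed geometric face template: a label raster on a square canvas.

    Not anatomically realistic — only the mask semantics matter to the
    extractor.
    """
    s = size / 256.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    lab = np.zeros((size, size), dtype=np.uint8)

    def put(region, mask):
        lab[mask] = LABELS[region]

    face = _ellipse(yy, xx, 136 * s, 128 * s, 100 * s, 78 * s)
    put("other_skin", face)
    put("forehead", face & _ellipse(yy, xx, 72 * s, 128 * s, 28 * s, 52 * s))
    for cx in (98, 158):  # periorbital patches around the eyes
        put("periorbital", face & _ellipse(yy, xx, 124 * s, cx * s, 17 * s, 25 * s))
    for cx in (84, 172):  # cheeks
        put("cheek", face & _ellipse(yy, xx, 152 * s, cx * s, 22 * s, 17 * s))
    put("nose", face & (np.abs(xx - 128 * s) <= 12 * s) & (yy >= 122 * s) & (yy <= 168 * s))
    put("chin", face & _ellipse(yy, xx, 216 * s, 128 * s, 14 * s, 26 * s))
    for c0, c1 in ((80, 118), (138, 176)):  # brows
        put("brows", face & (yy >= 103 * s) & (yy <= 111 * s) & (xx >= c0 * s) & (xx <= c1 * s))
    for cx in (98, 158):  # eyes
        put("eyes", face & _ellipse(yy, xx, 124 * s, cx * s, 7 * s, 14 * s))
    put("lips", face & _ellipse(yy, xx, 192 * s, 128 * s, 10 * s, 24 * s))
    return lab


def generate_face_panel(
    config: SynthConfig, n_faces: int | None = None, rng: np.random.Generator | None = None
) -> FacePanel:
    """Draw a panel of synthetic face images plus their region masks.

    Per-face region mean colours are sampled from ``region_palette`` with a
    shared within-face offset (fraction ``region_corr`` of skin-region
    variance), then i.i.d. Gaussian pixel noise is added in CIELAB with a
    per-face SD drawn uniformly from ``pixel_noise_sd_range``. Colours
    falling outside the sRGB gamut are clipped and recorded per face.
    """
    if n_faces is None:
        n_faces = config.n_faces_train
    if rng is None:
        rng = config.rng(stream=1)
    template = build_label_template(config.canvas)
    skin_regions = {"forehead", "cheek", "nose", "chin", "periorbital", "other_skin"}
    images, masks, ids = [], [], []
    truth_faces = []
    w = float(np.sqrt(config.region_corr))
    v = float(np.sqrt(1.0 - config.region_corr))
    for i in range(n_faces):
        fid = f"face{i:03d}"
        shared = rng.standard_normal(3)
        region_means: dict[str, list[float]] = {}
        lab_img = np.zeros((config.canvas, config.canvas, 3))
        for region, (mean, sd) in config.region_palette.items():
            mean, sd = np.asarray(mean, float), np.asarray(sd, float)
            z = rng.standard_normal(3)
            if region in skin_regions:
                m = mean + sd * (w * shared + v * z)
            elif region == "background":
                m = mean.copy()
            else:
                m = mean + sd * z
            region_means[region] = [float(x) for x in m]
            lab_img[template == LABELS[region]] = m
        noise_sd = float(rng.uniform(*config.pixel_noise_sd_range))
        fg = template != LABELS["background"]
        lab_img[fg] += noise_sd * rng.standard_normal((int(fg.sum()), 3))
        srgb, gamut = lab_to_srgb(lab_img, return_gamut_mask=True)
        truth_faces.append(
            {
                "face_id": fid,
                "region_means": region_means,
                "pixel_noise_sd": noise_sd,
                "n_gamut_clipped": int(gamut.sum()),
            }
        )
        images.append(srgb)
        masks.append(template.copy())
        ids.append(fid)
    return FacePanel(
        images, masks, ids,
        {"faces": truth_faces, "config_seed": int(config.seed), "canvas": config.canvas},
    )


# ---------------------------------------------------------------------------
# table-level generator


@dataclass
class FactorModel:
    """Loadings and scales of the latent-factor feature generator.

    Each feature j is ``base_mean_j + base_sd_j * (lambda_j f_{k(j)} +
    sqrt(1 - lambda_j^2) eps_j)``. The unit-variance factors share a
    common axis: ``f_k = w_k g + sqrt(1 - w_k^2) u_k``, so two factors
    correlate as ``w_k w_l`` (signed) and two features in different
    blocks as ``lambda_i lambda_j w_k w_l``.
    """

    factor_of: pd.Series  # feature -> factor name
    loading: pd.Series  # feature -> lambda in [0, 1]
    base_mean: pd.Series
    base_sd: pd.Series
    factor_weight: pd.Series  # factor -> signed common-axis weight w

    def implied_correlation(self, f1: str, f2: str) -> float:
        """Population correlation between two features under the model."""
        if f1 == f2:
            return 1.0
        r = self.loading[f1] * self.loading[f2]
        k, l = self.factor_of[f1], self.factor_of[f2]
        if k != l:
            r *= self.factor_weight[k] * self.factor_weight[l]
        return float(r)

    def implied_correlation_matrix(self) -> pd.DataFrame:
        lam = self.loading.to_numpy()
        w = self.factor_of.map(self.factor_weight).to_numpy()
        same = (
            self.factor_of.to_numpy()[:, None] == self.factor_of.to_numpy()[None, :]
        )
        cross = (lam * w)[:, None] * (lam * w)[None, :]
        within = lam[:, None] * lam[None, :]
        corr = np.where(same, within, cross)
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=self.loading.index, columns=self.loading.index)


_BASE_STATS = {  # (mean, SD) by (area kind, coordinate)
    ("skin", "L*"): (60.0, 3.0), ("skin", "a*"): (13.0, 2.0),
    ("skin", "b*"): (16.0, 2.0), ("skin", "C*"): (20.5, 2.2),
    ("skin", "h_ab"): (51.0, 4.0),
    ("Lip", "L*"): (45.0, 4.0), ("Lip", "a*"): (25.0, 3.0),
    ("Lip", "b*"): (14.0, 2.0), ("Lip", "C*"): (28.5, 3.0),
    ("Lip", "h_ab"): (29.0, 4.0),
    ("Brows", "L*"): (25.0, 4.0), ("Brows", "a*"): (6.0, 2.0),
    ("Brows", "b*"): (8.0, 2.0), ("Brows", "C*"): (10.0, 2.0),
    ("Brows", "h_ab"): (53.0, 6.0),
    ("Eyes", "L*"): (22.0, 4.0), ("Eyes", "a*"): (5.0, 1.5),
    ("Eyes", "b*"): (6.0, 1.5), ("Eyes", "C*"): (8.0, 1.8),
    ("Eyes", "h_ab"): (50.0, 6.0),
    ("mcdm", None): (3.0, 0.8),
    ("contrast", "L*"): (0.35, 0.07), ("contrast", "a*"): (0.25, 0.07),
    ("contrast", "b*"): (0.30, 0.07), ("contrast", "C*"): (0.30, 0.07),
    ("contrast", "h_ab"): (0.02, 0.05),
}

_COORD_FACTOR = {"L*": "lightness", "a*": "redness", "C*": "redness",
                 "b*": "yellowness", "h_ab": "hue"}


def _coord_of(name: str) -> str:
    for c in ("h_ab", "L*", "a*", "b*", "C*"):
        if name == c or name.endswith("_" + c):
            return c
    raise ValueError(name)


def default_factor_model(factor_weights: dict | None = None) -> FactorModel:
    """The default loadings: one factor per colour attribute, one per MCDM
    block, one per contrast feature; skin-area loadings 0.9 (L*) / 0.85,
    facial-feature colours 0.5, MCDM 0.85, contrasts 0.8."""
    factor_of, loading, mean, sd = {}, {}, {}, {}
    for name in FEATURE_NAMES:
        if name.startswith("MCDM"):
            factor_of[name] = "heterogeneity"
            loading[name] = 0.85
            mean[name], sd[name] = _BASE_STATS[("mcdm", None)]
            continue
        coord = _coord_of(name)
        if "_C_" in name:
            feat = name.split("_C_")[0]  # Eyes / Brows / Mouth
            factor_of[name] = f"contrast_{feat.lower()}"
            loading[name] = 0.8
            m, s = _BASE_STATS[("contrast", coord)]
            if feat == "Mouth" and coord in ("a*", "C*"):
                m = -m  # lips redder / more chromatic than skin
            mean[name], sd[name] = m, s
            continue
        area = name.split("_")[0] if "_" in name and not name.startswith(coord) else "skin"
        if area in ("Lip", "Brows", "Eyes"):
            factor_of[name] = _COORD_FACTOR[coord]
            loading[name] = 0.5
            mean[name], sd[name] = _BASE_STATS[(area, coord)]
        else:  # average or local skin
            factor_of[name] = _COORD_FACTOR[coord]
            loading[name] = 0.9 if coord == "L*" else 0.85
            mean[name], sd[name] = _BASE_STATS[("skin", coord)]
    idx = list(FEATURE_NAMES)
    weights = dict(DEFAULT_FACTOR_WEIGHTS if factor_weights is None else factor_weights)
    missing = set(factor_of.values()) - set(weights)
    if missing:
        raise ValueError(f"factor_weights lacks factors: {sorted(missing)}")
    if any(abs(v) > 1 for v in weights.values()):
        raise ValueError("factor weights must lie in [-1, 1]")
    return FactorModel(
        pd.Series(factor_of)[idx], pd.Series(loading)[idx],
        pd.Series(mean)[idx], pd.Series(sd)[idx], pd.Series(weights),
    )


def generate_feature_table(
    config: SynthConfig,
    n_faces: int | None = None,
    rng: np.random.Generator | None = None,
    model: FactorModel | None = None,
) -> tuple[pd.DataFrame, FactorModel]:
    """Draw a (faces × 65) feature table from the latent-factor model.

    Returns the realized table and the generating :class:`FactorModel`.
    Loadings outside [-1, 1] make the implied correlation matrix
    non-positive-semi-definite and are rejected.
    """
    if n_faces is None:
        n_faces = config.n_faces
    if rng is None:
        rng = config.rng(stream=2)
    if model is None:
        model = default_factor_model(config.factor_weights)
    lam = model.loading.to_numpy()
    if np.any(np.abs(lam) > 1.0):
        bad = model.loading[model.loading.abs() > 1.0].index.tolist()
        raise ValueError(
            "implied correlation matrix is not positive semi-definite: "
            f"|loading| > 1 for {bad}"
        )
    factors = sorted(model.factor_of.unique())
    wts = model.factor_weight[factors].to_numpy()
    g = rng.standard_normal((n_faces, 1))
    u = rng.standard_normal((n_faces, len(factors)))
    f = wts * g + np.sqrt(1.0 - wts**2) * u  # unit variance, corr w_k w_l
    fmap = {name: i for i, name in enumerate(factors)}
    cols = model.factor_of.map(fmap).to_numpy()
    eps = rng.standard_normal((n_faces, len(FEATURE_NAMES)))
    z = lam * f[:, cols] + np.sqrt(1.0 - lam**2) * eps
    table = model.base_mean.to_numpy() + model.base_sd.to_numpy() * z
    ids = [f"face{i:03d}" for i in range(n_faces)]
    df = pd.DataFrame(table, index=ids, columns=list(FEATURE_NAMES))
    df.index.name = "face_id"
    return df, model


def latent_scores(features: pd.DataFrame, config: SynthConfig) -> pd.Series:
    """The true latent attractiveness score of each face,
    ``s_f = sum_j beta_j z_j(f)`` with z the table-standardized feature."""
    missing = set(config.true_support) - set(features.columns)
    if missing:
        raise ValueError(f"features table lacks support columns: {sorted(missing)}")
    s = pd.Series(0.0, index=features.index)
    for name, beta in zip(config.true_support, config.true_beta):
        col = features[name].astype(float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"support feature {name!r} is constant")
        s = s + beta * (col - col.mean()) / sd
    return s


def face_appeal(features: pd.DataFrame, config: SynthConfig) -> pd.Series:
    """Colour-independent appeal residual of each face, ``N(0,
    face_noise_sd^2)``. A property of the face: drawn once per face and
    shared by every observer in both panels, so ratings stay internally
    consistent while colour explains only part of the score variance."""
    rng = config.rng(stream=5)
    d = config.face_noise_sd * rng.standard_normal(len(features))
    return pd.Series(d, index=features.index)


def generate_ratings(
    features: pd.DataFrame,
    config: SynthConfig,
    panel: str = "train",
    rng: np.random.Generator | None = None,
) -> RatingsPanel:
    """Draw an observer × face Likert panel (integers 1–7).

    Observer o's rating of face f is ``clamp(round(m + b_o + s_f + d_f +
    eps_of), 1, 7)`` with s the colour latent score, d the shared
    colour-independent face appeal, b observer bias and eps trial noise.
    The train panel covers the first ``n_faces_train`` faces; the test
    panel covers the first ``n_overlap_faces`` (re-rated with fresh
    observer noise) plus the ``n_faces_test`` new faces.
    """
    if panel not in ("train", "test"):
        raise ValueError("panel must be 'train' or 'test'")
    if rng is None:
        rng = config.rng(stream=3 if panel == "train" else 4)
    needed = config.n_faces_train if panel == "train" else config.n_faces
    if len(features) < needed:
        raise ValueError(
            f"need {needed} faces in the table for the {panel} panel, "
            f"got {len(features)}"
        )
    ids = list(features.index)
    if panel == "train":
        faces = ids[: config.n_faces_train]
        n_obs = config.n_observers_train
    else:
        faces = (
            ids[: config.n_overlap_faces]
            + ids[config.n_faces_train : config.n_faces_train + config.n_faces_test]
        )
        n_obs = config.n_observers_test
    s = (latent_scores(features, config) + face_appeal(features, config)).loc[
        faces
    ].to_numpy()
    bias = config.observer_bias_sd * rng.standard_normal(n_obs)
    eps = config.rating_noise_sd * rng.standard_normal((n_obs, len(faces)))
    raw = config.rating_midpoint + bias[:, None] + s[None, :] + eps
    lo, hi = SynthConfig.RATING_SCALE
    ratings = np.clip(np.round(raw), lo, hi).astype(int)
    obs_ids = [f"{panel[:2].upper()}{o:02d}" for o in range(n_obs)]
    df = pd.DataFrame(ratings, index=obs_ids, columns=faces)
    df.index.name = "observer_id"
    return RatingsPanel(df, site=panel)


@dataclass
class SynthStudy:
    """One complete synthetic study: features, two rating panels, truth."""

    features: pd.DataFrame  # train faces first, then test faces
    train_panel: RatingsPanel
    test_panel: RatingsPanel
    factor_model: FactorModel
    latent: pd.Series
    config: SynthConfig

    @property
    def train_faces(self) -> list[str]:
        return list(self.features.index[: self.config.n_faces_train])

    @property
    def test_faces(self) -> list[str]:
        n = self.config.n_faces_train
        return list(self.features.index[n : n + self.config.n_faces_test])

    @property
    def overlap_faces(self) -> list[str]:
        return list(self.features.index[: self.config.n_overlap_faces])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "features.csv")
        self.train_panel.to_long_csv(outdir / "ratings_train.csv")
        self.test_panel.to_long_csv(outdir / "ratings_test.csv")
        truth = {
            "true_support": list(self.config.true_support),
            "true_beta": list(self.config.true_beta),
            "latent_scores": {k: float(v) for k, v in self.latent.items()},
            "face_appeal": {
                k: float(v)
                for k, v in face_appeal(self.features, self.config).items()
            },
            "factor_of": self.factor_model.factor_of.to_dict(),
            "loading": self.factor_model.loading.to_dict(),
            "factor_weight": self.factor_model.factor_weight.to_dict(),
            "seed": int(self.config.seed),
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def generate_study(config: SynthConfig | None = None, **overrides) -> SynthStudy:
    """Generate a full table-level study under one config/seed."""
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    features, model = generate_feature_table(config)
    train = generate_ratings(features, config, "train")
    test = generate_ratings(features, config, "test")
    return SynthStudy(features, train, test, model, latent_scores(features, config), config)


def generate_image_study(config: SynthConfig | None = None, **overrides):
    """Image-level study: faces are rendered and the 65 features are
    *extracted* from the pixels, then ratings are drawn from the extracted
    features. Returns (FacePanel, SynthStudy with factor_model=None)."""
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    panel = generate_face_panel(config, n_faces=config.n_faces)
    features = extract_table(panel.images, panel.mask_sets(), face_ids=panel.face_ids)
    train = generate_ratings(features, config, "train")
    test = generate_ratings(features, config, "test")
    study = SynthStudy(
        features, train, test, None, latent_scores(features, config), config
    )
    return panel, study
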