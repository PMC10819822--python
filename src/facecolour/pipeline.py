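"""End-to-end orchestration of the four-step framework.

extract (or synthesize) → screen → fit the eight strategies → evaluate →
variable-count sweep, with every intermediate table written out and a
provenance record (package/library versions, per-stage seeds, config
hash) sufficient to regenerate every number in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import cluster_predictors, compare_models
from .models import fit_all, standardize
from .screen import (
    RatingsPanel,
    cronbach_alpha,
    cross_site_consistency,
    mean_ratings,
    pearson_screen,
)
from .synth import SynthConfig, generate_image_study, generate_study
from .varsim import DEFAULT_N_GRID, run_varcount

__all__ = ["PipelineConfig", "PipelineError", "run_framework"]


class PipelineError(RuntimeError):
    """A stage of the framework failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config drives the whole framework; all randomness flows from
    ``seed``, expanded deterministically per stage."""

    seed: int = 7
    source: str = "synth"  # synth | synth-image | files
    synth: dict = field(default_factory=dict)  # overrides for SynthConfig
    features_csv: str | None = None
    ratings_train_csv: str | None = None
    ratings_test_csv: str | None = None
    n_faces_train: int | None = None  # required for source=files
    screening_alpha: float = 0.05
    folds: int = 10
    n_grid: tuple = DEFAULT_N_GRID
    iterations: int = 30
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: int) -> int:
        return int(
            np.random.SeedSequence([int(self.seed), stage]).generate_state(1)[0]
            % (2**31 - 1)
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.source in ("synth", "synth-image"):
        synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
        if config.source == "synth":
            study = generate_study(synth_cfg)
        else:
            _, study = generate_image_study(synth_cfg)
        return (
            study.features,
            study.train_panel,
            study.test_panel,
            study.train_faces,
            study.test_faces,
            study.overlap_faces,
            study,
        )
    if config.source != "files":
        raise PipelineError("input", f"unknown source {config.source!r}")
    if not (config.features_csv and config.ratings_train_csv and config.ratings_test_csv):
        raise PipelineError("input", "source=files needs features and both ratings CSVs")
    features = pd.read_csv(config.features_csv, index_col="face_id")
    train_panel = RatingsPanel.from_long_csv(config.ratings_train_csv, site="train")
    test_panel = RatingsPanel.from_long_csv(config.ratings_test_csv, site="test")
    train_faces = [f for f in features.index if f in train_panel.ratings.columns]
    test_faces = [
        f for f in features.index
        if f in test_panel.ratings.columns and f not in train_panel.ratings.columns
    ]
    overlap = [f for f in train_faces if f in test_panel.ratings.columns]
    return features, train_panel, test_panel, train_faces, test_faces, overlap, None


def run_framework(config: PipelineConfig, outdir=None) -> dict:
    """Run the full framework; returns the report bundle as a dict and, if
    an output directory is configured, writes all artefacts there."""
    outdir = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        (features, train_panel, test_panel,
         train_faces, test_faces, overlap, study) = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("input", str(exc)) from exc

    bundle: dict = {"config_hash": config.config_hash()}

    try:
        a_tr, ci_tr = cronbach_alpha(train_panel)
        a_te, ci_te = cronbach_alpha(test_panel)
        consistency = {
            "cronbach_alpha_train": a_tr, "alpha_ci_train": ci_tr,
            "cronbach_alpha_test": a_te, "alpha_ci_test": ci_te,
        }
        scores_train = mean_ratings(train_panel)
        scores_test_all = mean_ratings(test_panel)
        if overlap:
            r, ci, degen = cross_site_consistency(
                scores_train.loc[overlap], scores_test_all.loc[overlap]
            )
            consistency.update(
                cross_site_r=r, cross_site_ci=ci, cross_site_n=len(overlap),
                degenerate=degen,
            )
        bundle["consistency"] = consistency
    except Exception as exc:
        raise PipelineError("consistency", str(exc)) from exc

    try:
        ytr = scores_train.loc[train_faces]
        yte = scores_test_all.loc[test_faces]
        screening = pearson_screen(
            features.loc[train_faces], ytr, alpha_level=config.screening_alpha
        )
        kept = screening.kept
        bundle["screening"] = screening
        if not kept:
            raise ValueError(
                "no feature passed screening at "
                f"p < {config.screening_alpha}; nothing to model"
            )
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    try:
        Xtr, params = standardize(features.loc[train_faces, kept])
        Xte = params.apply(features.loc[test_faces, kept])
        fold_seed = config.stage_seed(1)
        models = fit_all(Xtr, ytr, folds=config.folds, fold_seed=fold_seed)
        bundle["models"] = models
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        report = compare_models(models, (Xtr, ytr), (Xte, yte))
        top = models["EN"].selected or kept
        clusters = (
            cluster_predictors(features.loc[train_faces, top])
            if len(top) >= 2 else None
        )
        bundle["report"] = report
        bundle["clusters"] = clusters
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    try:
        var_seed = config.stage_seed(2)
        n_grid = sorted({n for n in config.n_grid if n <= len(kept)} | {len(kept)})
        varres = run_varcount(
            (Xtr, ytr), (Xte, yte), relevant=kept, n_grid=n_grid,
            iterations=config.iterations, seed=var_seed, folds=config.folds,
        )
        bundle["varsim"] = varres
    except Exception as exc:
        raise PipelineError("varsim", str(exc)) from exc

    provenance = {
        "package_version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(config),
        "config_hash": bundle["config_hash"],
        "stage_seeds": {"fit_fold_seed": fold_seed, "varsim_seed": var_seed},
        "n_screened": len(kept),
        "library_versions": _library_versions(),
    }
    bundle["provenance"] = provenance

    if outdir:
        _write_bundle(outdir, config, features, train_panel, test_panel,
                      scores_train, scores_test_all, bundle, study)
    return bundle


def _library_versions() -> dict:
    import pandas
    import scipy
    import sklearn

    return {"pandas": pandas.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__}


def _write_bundle(outdir, config, features, train_panel, test_panel,
                  scores_train, scores_test, bundle, study) -> None:
    outdir = Path(outdir)
    features.to_csv(outdir / "features.csv")
    train_panel.to_long_csv(outdir / "ratings_train.csv")
    test_panel.to_long_csv(outdir / "ratings_test.csv")
    scores_train.rename("score").to_csv(outdir / "scores_train.csv")
    scores_test.rename("score").to_csv(outdir / "scores_test.csv")
    bundle["screening"].to_csv(outdir / "screening.csv")
    with open(outdir / "consistency.json", "w") as fh:
        json.dump(bundle["consistency"], fh, indent=1)
    mdir = outdir / "models"
    mdir.mkdir(exist_ok=True)
    for name, model in bundle["models"].items():
        model.save(mdir / f"{name}.json")
    bundle["report"].save(outdir / "report")
    if bundle["clusters"] is not None:
        with open(outdir / "report" / "predictor_groups.json", "w") as fh:
            json.dump(
                {"leaf_order": bundle["clusters"]["leaf_order"],
                 "groups": bundle["clusters"]["groups"]},
                fh, indent=1,
            )
    bundle["varsim"].to_csv(outdir / "varsim.csv")
    if study is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(
                {"true_support": list(study.config.true_support),
                 "true_beta": list(study.config.true_beta)},
                fh, indent=1,
            )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(bundle["provenance"], fh, indent=1, default=str)
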