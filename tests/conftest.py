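import numpy as np
import pytest

from facecolour import (
    SynthConfig,
    generate_study,
    mean_ratings,
    pearson_screen,
    standardize,
)


@pytest.fixture(scope="session")
def default_study():
    """One table-level synthetic study under the default design."""
    return generate_study(seed=11)


@pytest.fixture(scope="session")
def screened_data(default_study):
    """Standardized screened train/test matrices + mean scores."""
    study = default_study
    ytr = mean_ratings(study.train_panel).loc[study.train_faces]
    yte = mean_ratings(study.test_panel).loc[study.test_faces]
    report = pearson_screen(study.features.loc[study.train_faces], ytr)
    Xtr, params = standardize(study.features.loc[study.train_faces, report.kept])
    Xte = params.apply(study.features.loc[study.test_faces, report.kept])
    return {"Xtr": Xtr, "ytr": ytr, "Xte": Xte, "yte": yte,
            "report": report, "study": study}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A small, fast configuration for image-level tests."""
    return SynthConfig(
        n_faces_train=4, n_faces_test=3, n_observers_train=5,
        n_observers_test=6, n_overlap_faces=3, canvas=96, seed=5,
    )
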