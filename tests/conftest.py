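"""Shared fixtures: session-scoped synthetic cohorts at the study's scale.

The expensive artifacts (the 900-cell feature matrix and the tuned
boosted-tree run with its label-shuffle control) are generated once per
session and shared across the tests that probe them.
"""

import numpy as np
import pytest

from islet_cytotyper.classify import CVSpec, ModelSpec, SearchSpec, cross_validate
from islet_cytotyper.preprocess import run_preprocessing
from islet_cytotyper.stability import evaluate, salzberg_test
from islet_cytotyper.synthetic_islet import SynthConfig, generate_feature_matrix

#: study-scale cohort: 900 cells, 2:1 beta:alpha, twofold lipofuscin effect,
#: beta-specific glucose-stimulated metabolic shift (generator defaults)
STUDY_SEED = 1234


@pytest.fixture(scope="session")
def study_matrix():
    cfg = SynthConfig(n_cells=900, seed=STUDY_SEED)
    return generate_feature_matrix(cfg)


@pytest.fixture(scope="session")
def small_matrix():
    """A quick 120-cell cohort for cheap structural tests."""
    cfg = SynthConfig(n_cells=120, seed=7)
    return generate_feature_matrix(cfg)


@pytest.fixture(scope="session")
def recovery_run(study_matrix):
    """Full tuned training run on the study-scale cohort plus its
    Salzberg label-shuffle control (identical pipeline on shuffled labels).
    """
    matrix, target = study_matrix
    prep = run_preprocessing(matrix, target, seed=STUDY_SEED)
    cv = CVSpec(n_folds=5, n_repeats=3, seed=STUDY_SEED)
    search = SearchSpec(strategy="sampled", budget=50, seed=STUDY_SEED)
    spec = ModelSpec("boosted-trees")
    model, report = cross_validate(prep.X_train, prep.y_train, spec,
                                   cv=cv, search=search)
    test_report = evaluate(model, prep.X_test, prep.y_test)
    salzberg = salzberg_test(prep.X_train, prep.y_train, prep.X_test,
                             prep.y_test, spec, cv=cv, search=search,
                             seed=STUDY_SEED, real_report=test_report,
                             real_model=model)
    return {"prep": prep, "model": model, "cv_report": report,
            "test_report": test_report, "salzberg": salzberg}
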