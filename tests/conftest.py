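import dataclasses

import numpy as np
import pytest

from prefog import preprocessing as pp
from prefog import synthetic as sg
from prefog.model import GaitCycleCNN, Hyperparameters
from prefog.pipeline import PipelineConfig, preprocess_and_match

#: small cohort for structural tests: quick to generate and train on
SMALL_COHORT_CONFIG = sg.CohortConfig(
    n_freezers=4,
    n_nolab_freezers=3,
    n_nonfreezers=2,
    n_controls=2,
    prefog_per_freezer=4,
    fgc_per_subject=5,
    delta=0.6,
    noise_sd=1.0,
    duration_range=(90, 115),
    stooped_fraction=0.25,
    seed=42,
)

#: fast hyperparameters for tests that only need a trained network
FAST_H = Hyperparameters(n_blocks=1, filters=8, kernel=9, epochs=20, lr0=6e-3,
                         schedule_midpoint=12.0, dropout=0.05, seed=0)


@pytest.fixture(scope="session")
def templates():
    return sg.make_joint_templates("typical", subject_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return sg.generate_cohort(SMALL_COHORT_CONFIG)


@pytest.fixture(scope="session")
def small_matched(small_cohort):
    cfg = PipelineConfig(cohort=SMALL_COHORT_CONFIG, seed=42)
    matched, eval_cycles, extra = preprocess_and_match(small_cohort, cfg)
    return matched, eval_cycles, extra


@pytest.fixture(scope="session")
def small_arrays(small_matched):
    _, eval_cycles, _ = small_matched
    return pp.dataset_arrays(eval_cycles)


@pytest.fixture(scope="session")
def trained_small(small_arrays):
    X, y, subjects = small_arrays
    return GaitCycleCNN(X, y, subjects, hyperparameters=FAST_H).fit(seed=0)
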