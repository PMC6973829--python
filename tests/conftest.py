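"""Shared fixtures: small synthetic datasets reused across test modules.

Everything is generated at reduced scale (tens of sensors, tens of
seconds) so the whole suite runs on one CPU in minutes; the statistical
structure is the same as at full scale.
"""

import numpy as np
import pytest

from megstates import GenConfig, generate_layout
from megstates.evaluate import ClassifierSpec
from megstates.experiments import ExperimentConfig, collect_features

NULL_EFFECTS = {"alpha": 0.0, "beta": 0.0, "lower_gamma": 0.0, "upper_gamma": 0.0}


@pytest.fixture(scope="session")
def small_layout():
    return generate_layout(24, 4, seed=1)


@pytest.fixture(scope="session")
def small_gen():
    return GenConfig(seed=5, n_subjects=2, n_repetitions=2, n_sensors=24,
                     n_motor_excluded=4, duration=40.0)


@pytest.fixture(scope="session")
def null_gen(small_gen):
    import dataclasses
    return dataclasses.replace(small_gen, effect_sizes=dict(NULL_EFFECTS))


@pytest.fixture(scope="session")
def planted_local_features(small_gen):
    """(X, y, index, meta) for local-10 wavelet features, planted effects."""
    cfg = ExperimentConfig(gen=small_gen, seed=1)
    return collect_features(cfg, scope="local-10")


@pytest.fixture(scope="session")
def null_local_features(null_gen):
    cfg = ExperimentConfig(gen=null_gen, seed=1)
    return collect_features(cfg, scope="local-10")


@pytest.fixture(scope="session")
def fast_svm():
    return ClassifierSpec(kind="svm-rbf", tune=False)
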