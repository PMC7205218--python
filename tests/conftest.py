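"""Shared fixtures: small synthetic scenes and one full pipeline run.

The full default-condition pipeline run is session-scoped because training
the surrogate for both orthoses dominates the suite's runtime; every test
that needs trained models or walking fields shares it.
"""

import numpy as np
import pytest

from fodeform.dataset import build_dataset
from fodeform.pipeline import PipelineConfig, run_pipeline
from fodeform.synthetic import (
    REGULAR_STIFFNESS,
    make_fo_model,
    simulate_training_session,
    simulate_walking_session,
)


@pytest.fixture(scope="session")
def sport_fo():
    return make_fo_model()


@pytest.fixture(scope="session")
def regular_fo():
    return make_fo_model(stiffness_k=REGULAR_STIFFNESS)


@pytest.fixture(scope="session")
def small_training_scene(sport_fo):
    """Cheap training scene (2 events/region quota) for structural tests."""
    return simulate_training_session(sport_fo, n_loads_per_region=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_training_scene):
    return build_dataset(small_training_scene, seed=8)


@pytest.fixture(scope="session")
def small_walking_scene(sport_fo):
    return simulate_walking_session(sport_fo, n_steps=3, seed=9)


@pytest.fixture(scope="session")
def pipeline_artifacts():
    """One full run under the default study conditions (both orthoses,
    8 subjects); shared by the end-to-end and acceptance tests."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
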