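import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cpmconn import GeneratorSpec, generate, make_atlas

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted study: 30-node connectomes, 10 negative true edges."""
    spec = GeneratorSpec(n_model=80, n_validation=50, n_control=36,
                         n_nodes=30, n_true_edges=10, seed=42)
    return generate(spec)


@pytest.fixture(scope="session")
def atlas30():
    return make_atlas(30, 6)


@pytest.fixture
def tiny_pheno():
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(6)],
        "score_total": [10.0, 12.0, np.nan, 9.0, 15.0, 11.0],
        "age": [12, 20, 30, 15, 22, 18],
        "sex": ["M", "M", "F", "M", "F", "M"],
        "mfd": [0.05, 0.25, 0.08, 0.10, 0.07, 0.12],
        "site": ["A", "A", "A", "B", "B", "B"],
        "fiq": [100, 110, 69, 95, 120, 105],
        "handedness": ["right", "right", "right", "mixed", "right", "right"],
        "n_timepoints": [200, 200, 200, 200, 90, 200],
        "max_motion_mm": [0.5, 0.4, 0.3, 0.2, 0.1, 2.5],
        "max_motion_deg": [0.5, 0.4, 0.3, 0.2, 0.1, 0.5],
    })
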