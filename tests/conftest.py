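import numpy as np
import pandas as pd
import pytest

import cogrisk as cr


@pytest.fixture(scope="session")
def default_features():
    """One default 70-participant feature-level cohort (features only)."""
    cfg = cr.GeneratorConfig(seed=11)
    return cr.generate_feature_table(cfg)[0]


@pytest.fixture(scope="session")
def small_cohort():
    """A small signal-level cohort (4 participants, full battery)."""
    cfg = cr.GeneratorConfig(n_participants=4, seed=23)
    return cr.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def task_matrix(features: pd.DataFrame, task_id: str) -> np.ndarray:
    g = features[features["task"] == task_id].sort_values("participant")
    return g[list(cr.FEATURE_NAMES)].to_numpy(dtype=float)
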