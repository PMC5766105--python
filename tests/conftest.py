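import numpy as np
import pandas as pd
import pytest

from sightabund import TruthConfig, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A two-year, three-stratum survey with known truth."""
    cfg = TruthConfig(years=(2005, 2006), N_ht=(40, 30, 20), seed=7)
    return simulate_survey(cfg)


@pytest.fixture(scope="session")
def micro_tables():
    """One sampled plot per stratum, one year, tiny augmentation sizes."""
    op = pd.DataFrame({
        "year": [2005, 2005, 2005],
        "stratum": [1, 2, 3],
        "plot": ["s1p1", "s2p1", "s3p1"],
        "y": [2, 3, 1],
        "x": [0.2, 0.5, 0.7],
    })
    des = pd.DataFrame({
        "year": [2005] * 3, "stratum": [1, 2, 3],
        "N": [5, 4, 3], "n": [1, 1, 1],
    })
    return op, des


@pytest.fixture(scope="session")
def trials_124():
    from sightabund import simulate_sightability_trials

    return simulate_sightability_trials(0.33, -0.99, R=124, seed=3)
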