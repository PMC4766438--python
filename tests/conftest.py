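import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import odorfusion as of

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


def keyed_series(values) -> pd.Series:
    """A response profile keyed by deterministic synthetic InChIKeys."""
    values = np.asarray(values, dtype=float)
    return pd.Series(values, index=[of.synthetic_inchikey(i) for i in range(len(values))])


@pytest.fixture
def diagonal_curve() -> of.FittedCurve:
    """The identity line y = x fitted on [0, 1]."""
    return of.FittedCurve(
        family="linear", params=np.array([0.0, 1.0]), orientation="forward",
        t_range=(0.0, 1.0),
    )


@pytest.fixture
def simulated_unit():
    """Default study-generation conditions: 3 distorted noisy studies."""
    cfg = of.SimulationConfig(seed=11)
    truth = of.simulate_ground_truth(cfg)
    datasets, meta = of.simulate_studies(truth, cfg)
    return truth, datasets, meta


@pytest.fixture
def small_matrix() -> of.ResponseMatrix:
    """A tiny SFR-reset consensus matrix with three units."""
    keys = [of.synthetic_inchikey(i) for i in range(6)] + [of.SFR_KEY]
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.uniform(0, 1, size=(7, 3)),
        index=keys,
        columns=["unitA", "unitB", "unitC"],
    )
    df.loc[of.SFR_KEY] = 0.0
    return of.ResponseMatrix(values=df, scale_state="sfr-reset")
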