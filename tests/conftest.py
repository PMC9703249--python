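import numpy as np
import pandas as pd
import pytest

from coopnet.data_model import (
    DyadicAttributeSet,
    MonadicAttributeTable,
    standardize_attributes,
)
from coopnet.synthetic import GeneratorConfig, fixture_library, generate_study


def make_attribute_inputs(n: int, seed: int = 0):
    """Raw monadic table + dyadic matrices for n actors."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "woman": rng.integers(0, 2, n),
            "age": rng.normal(44.01, 14.70, n).clip(18, 95),
            "education": rng.normal(5.5, 4.5, n).clip(0, 17),
            "wealth_log": rng.normal(12.62, 0.94, n),
            "reputation": rng.poisson(2.28, n).astype(float),
            "caste": rng.choice(["backward", "scheduled"], n),
            "married": rng.integers(0, 2, n),
            "immigrant": rng.integers(0, 2, n),
            "village": rng.choice(["T", "A"], n),
        }
    )
    pos = rng.uniform(0, 900, (n, 2))
    dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    logd = np.log(dist + 1)
    np.fill_diagonal(logd, 0)
    kin = np.triu((rng.random((n, n)) < 0.15), 1).astype(float)
    kin = kin + kin.T
    friend = (rng.random((n, n)) < 0.2).astype(float)
    np.fill_diagonal(friend, 0)
    hh = np.zeros((n, n))
    dyads = DyadicAttributeSet(
        {"kinship": kin, "friendship": friend, "same_household": hh, "log_distance": logd}
    )
    return MonadicAttributeTable(frame), dyads


@pytest.fixture(scope="session")
def attrs10():
    table, dyads = make_attribute_inputs(10, seed=42)
    return standardize_attributes(table, dyads)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library(seed=0)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across tests (n = 40)."""
    cfg = GeneratorConfig(n_per_village=20, seed=7)
    roster, table, dyads, attrs, w1, w2, schedule, spec, beta = generate_study(cfg)
    return {
        "roster": roster,
        "table": table,
        "dyads": dyads,
        "attrs": attrs,
        "wave1": w1,
        "wave2": w2,
        "schedule": schedule,
        "model": spec,
        "beta": beta,
    }


def random_wave(n: int, density: float, rng: np.random.Generator):
    from coopnet.data_model import NetworkWave

    adj = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return NetworkWave("w", adj)
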