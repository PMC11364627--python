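import numpy as np
import pandas as pd
import pytest

import resptypes as rt
from resptypes.schema import DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return rt.load_fixture("table2")


@pytest.fixture(scope="session")
def small_population():
    """Three-country, three-type synthetic population (well separated).

    Uses profiles 3, 6 and 7 (the most mutually distinct published types)
    so small-sample clustering tests are stable.
    """
    profiles = rt.load_fixture("table2").loc[[3, 6, 7]]
    fps = {
        "AAA": np.array([0.6, 0.2, 0.2]),
        "BBB": np.array([0.2, 0.6, 0.2]),
        "CCC": np.array([0.2, 0.2, 0.6]),
    }
    npc = {"AAA": 120, "BBB": 120, "CCC": 120}
    cfg = rt.GeneratorConfig(
        profiles=profiles, country_fingerprints=fps, n_per_country=npc,
        missing_rate=0.02, seed=424242,
    )
    matrix, labels = rt.sample_questionnaires(cfg)
    return cfg, matrix, labels


@pytest.fixture()
def complete_matrix():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.integers(1, 6, size=(30, 8)).astype(float),
        columns=list(DEFAULT_SCHEMA.items),
    )
    data.insert(0, "country", "XXX")
    return data
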