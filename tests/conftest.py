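import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

TWO_PI = 2.0 * np.pi


def make_images(rows):
    """Image table from (site, species, datetime, nf, nm, nfawn) tuples."""
    return pd.DataFrame(
        rows,
        columns=["site_id", "species", "datetime",
                 "n_adult_female", "n_adult_male", "n_fawn"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def vonmises_pair(rng):
    """Two n=2000 samples from vonMises(0, 2) and vonMises(pi, 2)."""
    s1 = rng.vonmises(0.0, 2.0, 2000) % TWO_PI
    s2 = rng.vonmises(np.pi, 2.0, 2000) % TWO_PI
    return s1, s2


@pytest.fixture
def toy_cohort():
    """4 subjects, one coyote death on day 2, no censoring."""
    return pd.DataFrame(
        {
            "animal_id": ["a", "b", "c", "d"],
            "stratum": "fawn",
            "start_day": 0,
            "end_day": [2, 77, 77, 77],
            "outcome": ["coyote", "survived", "survived", "survived"],
        }
    )
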