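import numpy as np
import pandas as pd
import pytest

from codi import SpectraSet, SpectralAxis, make_population, scenario_config


@pytest.fixture
def axis4():
    return SpectralAxis(np.array([1000.0, 1500.0, 2000.0, 2500.0]))


@pytest.fixture
def tiny_set(axis4):
    """3 measurements x 4 channels with distinct labels and metadata."""
    data = np.array([
        [0.1, 0.2, 0.3, 0.4],
        [1.0, 0.5, 0.25, 0.125],
        [2.0, 2.0, 2.0, 2.0],
    ])
    meta = pd.DataFrame({
        "id": ["a", "b", "c"],
        "subject": ["s1", "s2", "s3"],
        "visit": ["0", "0", "1"],
        "specimen": ["plasma"] * 3,
        "batch": ["study0:A"] * 3,
        "provenance": ["experimental"] * 3,
    })
    return SpectraSet(axis=axis4, data=data, labels=np.array(["x", "y", "z"]),
                      meta=meta)


@pytest.fixture(scope="session")
def frozen_scenario():
    """The default 32-individual identification scenario at seed 0."""
    return make_population(scenario_config(rng_seed=0))
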