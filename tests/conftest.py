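import numpy as np
import pandas as pd
import pytest

from netsynergy.pipeline import PipelineInputs
from netsynergy.synthetic import SyntheticScenario, generate


@pytest.fixture(scope="session")
def default_data():
    """The reference planted scenario (seed 7) shared across tests."""
    return generate(SyntheticScenario())


@pytest.fixture(scope="session")
def default_inputs(default_data):
    d = default_data
    return PipelineInputs(
        ppi=d.ppi,
        mutations=d.mutations,
        tumor=d.tumor,
        normal=d.normal,
        profiles=d.profiles,
        driver=d.truth.driver,
        bliss=d.bliss,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
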