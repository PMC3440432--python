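import dataclasses

import numpy as np
import pytest

from thrombogen.kinetics import PHYSIOLOGIC_MEAN, SimulationConfig, simulate
from thrombogen.model import load_default_model, select_submodel


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def base_model(model):
    return select_submodel(model, False)


@pytest.fixture(scope="session")
def control_timecourse(model):
    """Mean physiologic control under the default configuration (cached)."""
    return simulate(model, PHYSIOLOGIC_MEAN, SimulationConfig())


def random_composition(rng, subject_id="rand"):
    """A composition drawn uniformly from the observed kindred ranges."""
    from thrombogen.kinetics import _OBSERVED_RANGE

    values = {attr: rng.uniform(lo, hi) for attr, (lo, hi) in _OBSERVED_RANGE.items()}
    return dataclasses.replace(PHYSIOLOGIC_MEAN, subject_id=subject_id, **values)
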