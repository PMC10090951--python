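import numpy as np
import pytest
from hypothesis import settings

import gtpase_circuit as gc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from gtpase_circuit.synthetic import SyntheticSpec, generate_timecourses


@pytest.fixture(scope="session")
def params():
    return gc.default_parameters()


@pytest.fixture(scope="session")
def coupled():
    return gc.ModelVariant.coupled()


@pytest.fixture(scope="session")
def basal(params, coupled):
    """Basal (stimulus 0) steady state of the coupled circuit."""
    return gc.pre_equilibrate(params, coupled)


@pytest.fixture(scope="session")
def stimulated_ss(params, coupled):
    """Steady state under the 50 nM EGF equivalent stimulus."""
    return gc.pre_equilibrate(params, coupled, gc.STIMULUS_50NM)


@pytest.fixture(scope="session")
def synthetic_data(params):
    """Default synthetic fold-change datasets plus ground-truth traces."""
    spec = SyntheticSpec(params=params, seed=11)
    datasets, truth = generate_timecourses(spec)
    return spec, datasets, truth
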