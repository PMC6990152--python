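import numpy as np
import pytest
from hypothesis import settings

import hergtemp as ht

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def herg_params():
    """Representative room-temperature hERG parameter magnitudes."""
    return ht.KineticParameters(
        g=0.1524, p1=2.26e-4, p2=0.0699, p3=3.45e-5, p4=0.05462,
        p5=0.0873, p6=8.91e-3, p7=5.15e-3, p8=0.03158, temperature_C=25.0)


@pytest.fixture(scope="session")
def cond25():
    return ht.IonicConditions.at_celsius(25.0)


@pytest.fixture(scope="session")
def staircase():
    return ht.builtin_protocol("staircase-fixture")


@pytest.fixture(scope="session")
def mini_protocol():
    """Short informative step protocol used for fast inference tests."""
    return ht.StepProtocol.from_steps(
        [(100.0, -80.0), (500.0, 40.0), (200.0, -120.0), (500.0, 0.0),
         (300.0, -40.0), (200.0, -120.0), (200.0, -80.0)])


@pytest.fixture(scope="session")
def temp_truth():
    return ht.default_temperature_truth()


@pytest.fixture(scope="session")
def truth25(temp_truth):
    return ht.parameters_at_temperature(temp_truth,
                                        ht.celsius_to_kelvin(25.0))


@pytest.fixture(scope="session")
def truth37(temp_truth):
    return ht.parameters_at_temperature(temp_truth,
                                        ht.celsius_to_kelvin(37.0))


@pytest.fixture(scope="session")
def noisy_mini_well(temp_truth, mini_protocol):
    """One noisy well on the mini protocol, with its generating truth."""
    truth = ht.hierarchical_truth_at(temp_truth, 25.0, log_sd=np.zeros(9))
    ds = ht.generate_dataset(truth, mini_protocol, 1, seed=3, dt=1.0)
    return ds.wells[0]


@pytest.fixture(scope="session")
def mini_well_fit(noisy_mini_well, mini_protocol, cond25):
    return ht.fit_well(noisy_mini_well.trace, mini_protocol, cond25,
                       n_starts=6, seed=5)
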