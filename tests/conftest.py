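import numpy as np
import pytest

from cppopt import (CppoptConfig, VirtualPatientSpec, compute_cppopt,
                    simulate_patient)
from cppopt.timeseries import SampledSeries


@pytest.fixture(scope="session")
def new_config():
    return CppoptConfig()


@pytest.fixture(scope="session")
def prev_config():
    return CppoptConfig.previous()


@pytest.fixture(scope="session")
def patient_10h():
    """One gap-free 10-h virtual patient with true optimum 75 mmHg."""
    spec = VirtualPatientSpec(duration=36000.0, true_opt=75.0, seed=1)
    abp, icp = simulate_patient(spec)
    return spec, abp, icp


@pytest.fixture(scope="session")
def run_10h_new(patient_10h, new_config):
    _, abp, icp = patient_10h
    return compute_cppopt(abp, icp, new_config)


@pytest.fixture(scope="session")
def run_10h_prev(patient_10h, prev_config):
    _, abp, icp = patient_10h
    return compute_cppopt(abp, icp, prev_config)


def make_series(values, dt=60.0, valid=None):
    return SampledSeries(np.asarray(values, float), dt, valid=valid)


@pytest.fixture
def series_factory():
    return make_series
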