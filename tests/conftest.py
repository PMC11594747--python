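import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mfphnr as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def elements():
    return m.build_dartboard()


@pytest.fixture(scope="session")
def grid():
    return m.build_posterior_pole_grid()


@pytest.fixture(scope="session")
def reference_cohort():
    return m.load_reference_cohort()


@pytest.fixture(scope="session")
def reference_summaries():
    return m.load_reference_summaries()


@pytest.fixture(scope="session")
def control_summaries(reference_summaries):
    return reference_summaries[reference_summaries["group"] == "control"]


@pytest.fixture
def waveform_params():
    return m.WaveformParams()


@pytest.fixture
def small_trace_set(elements, waveform_params):
    """Noise-free order-6 recording of the first five elements."""
    mseq = m.generate_mseq(6)
    return m.simulate_trace_set(elements[:5], mseq, waveform_params,
                                noise_sd=0.0, seed=0)
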