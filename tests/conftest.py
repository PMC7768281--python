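import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratiospec import (AperiodicParams, PeakParams, SpectralParams,
                       default_freqs, simulate_spectrum)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None)
settings.load_profile("suite")


@pytest.fixture
def freqs():
    return default_freqs()


@pytest.fixture
def three_peak_params():
    """Canonical study spectrum with fit-compatible (>= 1 Hz) peak widths."""
    return SpectralParams(
        AperiodicParams(0.0, 1.0),
        (PeakParams(6.0, 0.5, 1.5), PeakParams(10.0, 0.5, 1.5),
         PeakParams(21.5, 0.5, 1.5)),
        noise_sd=0.0)


@pytest.fixture
def pure_aperiodic():
    return SpectralParams(AperiodicParams(0.0, 1.0), (), noise_sd=0.0)


@pytest.fixture
def one_over_f_spectrum(pure_aperiodic):
    return simulate_spectrum(pure_aperiodic)
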