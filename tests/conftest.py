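import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ionfold",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ionfold")


@pytest.fixture
def dyes():
    """TAMRA/FAM photophysics with no direct acceptor excitation at 494 nm."""
    from ionfold.fret_core import DyePhotophysics

    return DyePhotophysics()


@pytest.fixture
def table_classes():
    """Two-class ITC truth: site-specific and backbone classes."""
    from ionfold import synthetic_data as sd

    return [sd.ITC_CLASS1_TRUTH, sd.ITC_CLASS2_TRUTH]


@pytest.fixture
def itc_protocol():
    """50 x 10 µL of 0.85 mM titrant into 16 µM junction, 1.4 mL cell."""
    from ionfold.synthetic_data import default_itc_experiment

    return default_itc_experiment()


@pytest.fixture
def gaussian_spectrum_factory():
    from ionfold.fret_core import Spectrum, SpectrumRole

    def make(center, sigma, amplitude, wl_lo, wl_hi, step=0.5,
             role=SpectrumRole.DONOR_EMISSION, baseline=0.0):
        wl = np.arange(wl_lo, wl_hi + step, step)
        return Spectrum(
            wl, amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2) + baseline,
            role,
        )

    return make
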