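import numpy as np
import pytest

from dimersig import (
    OpticsCalibration,
    PWM,
    PlantSpec,
    Species,
    builtin_probes,
    detect_bursts,
    generate_peak_set,
    simulate_photon_trace,
)


@pytest.fixture(scope="session")
def probes():
    return builtin_probes()


@pytest.fixture(scope="session")
def sox_pwm():
    return PWM.from_consensus("AACAAT")


@pytest.fixture(scope="session")
def dimer_trace():
    """100 s trace of pure 1-green/1-red complexes at default optics."""
    return simulate_photon_trace([Species(1, 1, 1.0)], OpticsCalibration(),
                                 duration_s=100.0, seed=11)


@pytest.fixture(scope="session")
def dimer_events(dimer_trace):
    return detect_bursts(dimer_trace)


@pytest.fixture(scope="session")
def planted_peaks():
    """300 uniform-background 500-bp peaks, 40% carrying the IR5 core."""
    spec = PlantSpec(half_site="AACAAT", gap=5, spacer="gcggc",
                     orientation="inverted", plant_fraction=0.4,
                     peak_length=500)
    return generate_peak_set(300, spec, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
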