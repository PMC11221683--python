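import numpy as np
import pytest

from wingsync import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def locked_recording():
    """Continuous phase-locked flight with moderate sensor noise."""
    return simulate_recording(SimConfig(duration_s=2.0, noise_sd=2.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_recording():
    """Continuous phase-locked flight, no noise and no jitter."""
    return simulate_recording(SimConfig(duration_s=2.0, seed=12))


@pytest.fixture(scope="session")
def no_flight_recording():
    """Rest-level recording with sparse isolated single wing beats."""
    return simulate_recording(
        SimConfig(coupling_mode="no_flight", duration_s=5.0, noise_sd=2.0, seed=13)
    )


@pytest.fixture(scope="session")
def drift_recording():
    """Independently drifting wings: frequency mismatch plus phase diffusion."""
    return simulate_recording(
        SimConfig(coupling_mode="drift", duration_s=10.0, noise_sd=2.0,
                  phase_jitter_sd=0.02, freq_mismatch_hz=15.0, seed=6)
    )
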