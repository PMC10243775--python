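import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netgc.source_model import SourceSpace
from netgc.synthetic_data import (make_forward_model, make_var2_model,
                                  simulate_recording,
                                  simulate_source_activity)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: labels for small ad-hoc spaces; the first two are FPC
SMALL_LABELS = ["precentral", "postcentral", "cuneus", "insula",
                "fusiform", "lingual", "bankssts", "precuneus",
                "superiorfrontal", "supramarginal"]


@pytest.fixture(scope="session")
def space5():
    return SourceSpace.from_labels(SMALL_LABELS[:5], k_components=1)


@pytest.fixture(scope="session")
def space6():
    return SourceSpace.from_labels(SMALL_LABELS[:6], k_components=1)


@pytest.fixture(scope="session")
def space10():
    return SourceSpace.from_labels(SMALL_LABELS, k_components=1)


def make_planted_recording(space, edges, seed, n_samples=750, n_sensors=16,
                           noise_frac=0.25, coupling=0.6, fs=50.0):
    """Sources from a planted sparse VAR(2), observed through a random
    near-orthogonal forward matrix with relative sensor noise."""
    model = make_var2_model(space, edges, coupling, seed=seed,
                            pole_radius_range=(0.75, 0.9), fs=fs)
    x = simulate_source_activity(model, n_samples, seed=seed + 1000)
    gain = make_forward_model(space, n_sensors, seed=seed + 2000)
    signal_rms = float(np.sqrt(np.mean((gain @ x) ** 2)))
    rec = simulate_recording(x, gain, noise_frac * signal_rms, fs,
                             seed=seed + 3000)
    return model, x, gain, rec
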