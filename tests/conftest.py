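import numpy as np
import pytest
from hypothesis import settings

from optokit import SpikeTrain, StimProtocol, SynthConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def short_chr2_protocol():
    """Two 20 Hz trains of 100 pulses with a short inter-train gap."""
    return StimProtocol(kind="pulse_train", frequency_hz=20.0,
                        pulses_per_train=100, n_trains=2,
                        inter_train_interval_s=10.0)


@pytest.fixture
def nphr_protocol():
    """Thirty 10-s silencing epochs spaced 30 s apart."""
    return StimProtocol(kind="continuous", light_duration_s=10.0,
                        n_trains=30, inter_train_interval_s=30.0)


@pytest.fixture
def clean_config():
    """Deterministic unit-fidelity cell: every pulse evokes one spike,
    no spontaneous activity."""
    return SynthConfig(seed=7, spont_rate_hz=0.0, evoked_prob=1.0,
                       doublet_prob=0.0)


def poisson_train(seed, rate_hz=5.0, duration_s=2000.0):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    t = np.unique(rng.uniform(0, duration_s, n))
    return SpikeTrain(t, duration_s, source="ground_truth")


def phasic_times(seed, n_target=10_000, rate_hz=5.0, depth=0.9, period_s=0.5):
    """Sinusoid-modulated inhomogeneous Poisson spike times (thinning)."""
    rng = np.random.default_rng(seed)
    duration = n_target / rate_hz
    rmax = rate_hz * (1 + depth)
    cand = np.sort(rng.uniform(0, duration, rng.poisson(rmax * duration)))
    keep = rng.uniform(0, rmax, cand.size) < rate_hz * (
        1 + depth * np.sin(2 * np.pi * cand / period_s))
    return cand[keep]
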