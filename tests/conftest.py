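import numpy as np
import pandas as pd
import pytest

from decayomics import SimConfig, generate_arrays, generate_truth

PAPER_TIMES = np.array(
    [0.0, 2.0, 8.0, 15.0, 0.0, 5.0, 10.0, 18.0, 0.0, 3.0, 12.0, 30.0]
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-transcript default-condition dataset shared across tests."""
    cfg = SimConfig(n_transcripts=300, seed=42)
    truth = generate_truth(cfg)
    probes, sheet = generate_arrays(truth, cfg)
    return cfg, truth, probes, sheet


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free, background-free arrays: the exact decay law."""
    cfg = SimConfig(
        n_transcripts=120,
        seed=7,
        noise_sd_ln=0.0,
        bio_sd_ln=0.0,
        background_mean=0.0,
        background_sd=0.0,
    )
    truth = generate_truth(cfg)
    probes, sheet = generate_arrays(truth, cfg)
    return cfg, truth, probes, sheet


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_timecourse(k, c0=100.0, times=PAPER_TIMES, tau=0.0, noise=0.0, rng=None):
    """Synthesize one ln-linear chase series (helper, not a fixture)."""
    t = np.asarray(times, dtype=float)
    decay = np.where(t <= tau, 1.0, np.exp(-k * (t - tau)))
    y = c0 * decay
    if noise > 0:
        y = y * np.exp(rng.normal(0.0, noise, size=t.size))
    return t, y
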