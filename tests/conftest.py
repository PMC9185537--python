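import numpy as np
import pytest

from dayfactor import (
    DFSeries,
    EISDataset,
    ForecasterConfig,
    df_series,
    fit_and_resample,
    mean_over_channels,
    scenario_preset,
    simulate_dataset,
)


def random_dataset(rng, n_days=5, n_freqs=6, n_channels=4, with_phase=False):
    """A valid random EIS dataset with magnitudes on the soak-test scale."""
    days = np.cumsum(rng.integers(1, 4, size=n_days))
    freqs = np.sort(rng.uniform(0.1, 2e6, size=n_freqs))
    mag = 10 ** rng.uniform(3.5, 6.5, size=(n_days, n_freqs, n_channels))
    phase = rng.uniform(-90, 0, size=mag.shape) if with_phase else None
    return EISDataset(days=days, frequencies=freqs, magnitude=mag, phase=phase)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, with_phase=True)


@pytest.fixture(scope="session")
def fast_config():
    """Shrunk training profile for protocol-level (non-accuracy) tests."""
    return ForecasterConfig(hidden_units=32, epochs=50, seed=7)


@pytest.fixture(scope="session")
def linear_signal():
    """Noise-free linear-trend DF signal: slope 0.02/day over days 1..11."""
    days = np.arange(1, 12)
    raw = 0.98 + 0.02 * days
    series = DFSeries(days=days, raw=raw, normalized=raw / raw[0])
    return fit_and_resample(series, samples_per_day=10)


@pytest.fixture(scope="session")
def dip_then_rise_signal():
    """Smoothed DF of the noise-free dip_then_rise preset."""
    scenario = scenario_preset("dip_then_rise")
    scenario.noise_sigma = 0.0
    scenario.channel_count = 1
    series = df_series(mean_over_channels(simulate_dataset(scenario)))
    return fit_and_resample(series, samples_per_day=10)
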