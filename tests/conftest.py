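"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from duetsync.timeseries import TimeSeries
from duetsync.wavelet import FrequencyGrid, log_frequency_grid


def sinusoid(
    freq_hz: float,
    duration_s: float = 120.0,
    rate_hz: float = 25.0,
    phase_rad: float = 0.0,
    amplitude: float = 1.0,
) -> TimeSeries:
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return TimeSeries(amplitude * np.sin(2 * np.pi * freq_hz * t + phase_rad), rate_hz)


def direct_morlet(
    x: np.ndarray, rate_hz: float, freq_hz: float, omega0: float = 6.0
) -> np.ndarray:
    """Independent time-domain oracle: literal convolution with the sampled
    Morlet kernel (dt/s) * pi^(-1/4) * exp(i*omega0*u/s) * exp(-u^2/(2 s^2)),
    truncated at +-8 scales where the Gaussian tail is < 1e-13."""
    dt = 1.0 / rate_hz
    s = omega0 / (2 * np.pi * freq_hz)
    half = int(np.ceil(8 * s / dt))
    u = np.arange(-half, half + 1) * dt
    kernel = (
        (dt / s)
        * (np.pi ** -0.25)
        * np.exp(1j * omega0 * u / s)
        * np.exp(-(u ** 2) / (2 * s ** 2))
    )
    return np.convolve(x, kernel, mode="same")


@pytest.fixture
def movement_grid() -> FrequencyGrid:
    return log_frequency_grid(0.3, 2.0, 20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
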