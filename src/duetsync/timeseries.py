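"""Uniformly sampled scalar time series — the currency passed between stages.

Every stage of the pipeline (movement traces, audio envelopes, wavelet band
summaries, annotation label tracks) exchanges data as a :class:`TimeSeries`:
a 1-D array of values, a sample rate in Hz, and the time offset of the first
sample in seconds. Time is always seconds, anchored to the video stream;
intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : array-like of float
        Sample values. At least two samples. NaN is permitted only as an
        explicit missing-value marker produced by masking operations;
        analysis entry points (e.g. the wavelet transform) reject NaN.
    rate_hz : float
        Sampling rate in samples per second; must be positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("TimeSeries requires at least two samples")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        """Duration covered by the samples, ``n / rate`` seconds."""
        return self.values.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate_hz

    def crop(self, start_s: float, stop_s: float) -> "TimeSeries":
        """Return the samples whose timestamps lie in ``[start_s, stop_s)``."""
        t = self.times
        keep = (t >= start_s) & (t < stop_s)
        idx = np.flatnonzero(keep)
        if idx.size < 2:
            raise ValueError("crop window retains fewer than two samples")
        return TimeSeries(self.values[idx], self.rate_hz, t0=t[idx[0]])

    def resample_to(self, rate_hz: float, times: np.ndarray | None = None) -> "TimeSeries":
        """Linear-interpolation resampling onto a new uniform grid.

        The pipeline's signals are slow relative to every sampling rate in
        play (band energies vary over seconds), so plain interpolation is
        adequate and keeps the operation exactly reproducible.
        """
        if times is None:
            n_new = max(2, int(round(self.duration_s * rate_hz)))
            times = self.t0 + np.arange(n_new) / rate_hz
        new_vals = np.interp(times, self.times, self.values)
        return TimeSeries(new_vals, rate_hz, t0=float(times[0]))


@dataclass
class RadialSignal:
    """Detrended, [0, 1]-normalized radial movement signal of one performer."""

    rho: TimeSeries

    def __post_init__(self) -> None:
        v = self.rho.values
        if np.isnan(v).any():
            raise ValueError("RadialSignal must not contain NaN")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("RadialSignal values must lie in [0, 1]")
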