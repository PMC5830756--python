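"""Continuous Morlet wavelet and cross-wavelet analysis.

The coordination measure at the centre of the pipeline is the cross-wavelet
transform (CWT) of the two performers' movement signals. Each signal is first
wavelet-transformed with a complex Morlet mother wavelet

    psi(u) = pi^(-1/4) * exp(i * omega0 * u) * exp(-u^2 / 2),

scaled so that the pseudo-frequency of scale ``s`` (seconds) is
``f = omega0 / (2 pi s)``. With the default ``omega0 = 6`` the pseudo-frequency
is, for practical purposes, the inverse period. The cross-wavelet coefficient
is the pointwise product of one transform with the complex conjugate of the
other; its squared modulus after Bartlett (triangular) smoothing along time is
the joint "energy" of the two signals at each (frequency, time) cell, and its
argument is their momentary phase difference (lead/lag).

Sign convention: ``phase = arg(W_a * conj(W_b))`` is **positive when b lags a**
— delaying the second signal by a quarter period yields a phase of +pi/2.

Edge effects are tracked with a cone of influence (COI): a coefficient is
flagged as edge-affected when its time is within ``sqrt(2) * s`` (the e-folding
time of the wavelet envelope) of either end of the series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .timeseries import TimeSeries

__all__ = [
    "FrequencyGrid",
    "FrequencyBand",
    "WaveletSpectrum",
    "CrossWaveletResult",
    "log_frequency_grid",
    "band_bank",
    "PREDICTOR_BAND_CENTERS",
    "COOCCURRENCE_BAND_CENTERS",
    "predictor_bands",
    "cooccurrence_bands",
    "broad_band",
    "morlet_wt",
    "cross_wavelet",
    "band_energy",
    "band_phase",
    "summed_wt_energy",
    "cooccurrence_density",
    "amplitude_profile",
    "save_spectrum",
    "load_spectrum",
]

#: Centre frequencies (Hz) of the five non-overlapping narrow predictor bands.
PREDICTOR_BAND_CENTERS = (0.3, 0.4, 0.6, 0.9, 2.0)

#: Centre frequencies (Hz) of the seven bands used for the co-occurrence density.
COOCCURRENCE_BAND_CENTERS = (0.29, 0.33, 0.40, 0.50, 0.67, 1.00, 2.00)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing analysis frequencies plus how they were spaced."""

    frequencies_hz: np.ndarray
    spacing: str = "log"
    voices_per_octave: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if (f <= 0).any() or (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be strictly increasing and positive")

    def __len__(self) -> int:
        return self.frequencies_hz.size


@dataclass(frozen=True)
class FrequencyBand:
    """A contiguous frequency band ``[low_hz, high_hz)`` with a nominal centre."""

    center_hz: float
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (self.low_hz < self.center_hz < self.high_hz):
            raise ValueError(
                f"band requires low < center < high, got "
                f"({self.low_hz}, {self.center_hz}, {self.high_hz})"
            )


def log_frequency_grid(
    low_hz: float, high_hz: float, voices_per_octave: int = 20
) -> FrequencyGrid:
    """Log-spaced frequency grid with a fixed number of voices per octave.

    Both endpoints are included; the grid therefore has
    ``ceil(voices * log2(high/low)) + 1`` points.
    """
    if low_hz <= 0 or high_hz <= low_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    n_oct = np.log2(high_hz / low_hz)
    n = int(np.ceil(n_oct * voices_per_octave)) + 1
    freqs = low_hz * 2.0 ** (np.linspace(0.0, n_oct, n))
    freqs[-1] = high_hz
    return FrequencyGrid(freqs, spacing="log", voices_per_octave=voices_per_octave)


def band_bank(
    centers: tuple[float, ...],
    low_edge: float | None = None,
    high_edge: float | None = None,
) -> list[FrequencyBand]:
    """Non-overlapping contiguous bands around the given centre frequencies.

    Interior edges are geometric midpoints ``sqrt(c_i * c_{i+1})`` of adjacent
    centres (log-frequency symmetry). Outer edges default to log-symmetric
    extensions of the first/last interior edge, or can be pinned explicitly.
    """
    c = np.asarray(centers, dtype=float)
    if (np.diff(c) <= 0).any():
        raise ValueError("band centres must be strictly increasing")
    inner = np.sqrt(c[:-1] * c[1:])
    lo = low_edge if low_edge is not None else c[0] ** 2 / inner[0]
    hi = high_edge if high_edge is not None else c[-1] ** 2 / inner[-1]
    edges = np.concatenate([[lo], inner, [hi]])
    return [
        FrequencyBand(center_hz=float(c[i]), low_hz=float(edges[i]), high_hz=float(edges[i + 1]))
        for i in range(c.size)
    ]


def predictor_bands() -> list[FrequencyBand]:
    """The five narrow movement-predictor bands (centres 0.3-2.0 Hz).

    Outer edges are pinned at 0.26 and 2.3 Hz so the bank tiles the analysis
    range 0.3-2.0 Hz with a small margin on either side.
    """
    return band_bank(PREDICTOR_BAND_CENTERS, low_edge=0.26, high_edge=2.3)


def cooccurrence_bands() -> list[FrequencyBand]:
    """The seven co-occurrence bands (centres 0.29-2.0 Hz)."""
    return band_bank(COOCCURRENCE_BAND_CENTERS)


def broad_band(low_hz: float = 0.3, high_hz: float = 2.0) -> FrequencyBand:
    """The broad analysis band; centre is the geometric mean of the edges."""
    return FrequencyBand(
        center_hz=float(np.sqrt(low_hz * high_hz)),
        low_hz=low_hz,
        # nudge the top edge so a grid endpoint at high_hz falls inside the
        # half-open band
        high_hz=high_hz * (1 + 1e-9),
    )


@dataclass
class WaveletSpectrum:
    """Complex Morlet coefficients of one signal over (frequency x time)."""

    coefficients: np.ndarray  # complex, shape (n_freq, n_time)
    grid: FrequencyGrid
    times: np.ndarray  # seconds, shape (n_time,)
    coi_mask: np.ndarray  # bool, True where edge-affected
    source_rate_hz: float
    omega0: float = 6.0

    def __post_init__(self) -> None:
        nf, nt = self.coefficients.shape
        if nf != len(self.grid) or nt != self.times.size:
            raise ValueError("coefficient matrix shape does not match grid x times")
        if self.coi_mask.shape != self.coefficients.shape:
            raise ValueError("coi_mask shape must match coefficients")

    @property
    def energy(self) -> np.ndarray:
        """Squared modulus of the coefficients (power convention)."""
        return np.abs(self.coefficients) ** 2

    @property
    def amplitude(self) -> np.ndarray:
        """Modulus of the coefficients."""
        return np.abs(self.coefficients)


@dataclass
class CrossWaveletResult:
    """Cross-wavelet coefficients, energy and phase of a signal pair."""

    cross_coefficients: np.ndarray  # complex (n_freq, n_time), smoothed
    energy: np.ndarray  # |smoothed cross|^2
    phase: np.ndarray  # arg in (-pi, pi]
    grid: FrequencyGrid
    times: np.ndarray
    coi_mask: np.ndarray
    source_rate_hz: float
    smoothing_window_s: float = 1.0
    phase_from_smoothed: bool = True

    def __post_init__(self) -> None:
        shapes = {
            self.cross_coefficients.shape,
            self.energy.shape,
            self.phase.shape,
            self.coi_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("cross-wavelet planes must share one shape")
        if (self.energy < 0).any():
            raise ValueError("energy must be non-negative")


def _scales_s(grid: FrequencyGrid, omega0: float) -> np.ndarray:
    # pseudo-frequency mapping f = omega0 / (2 pi s)
    return omega0 / (2.0 * np.pi * grid.frequencies_hz)


def _coi_mask(n: int, dt: float, scales: np.ndarray) -> np.ndarray:
    """True where the sample is within sqrt(2)*s of either series edge."""
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    return t_edge[None, :] < (np.sqrt(2.0) * scales)[:, None]


def morlet_wt(
    series: TimeSeries, grid: FrequencyGrid, omega0: float = 6.0
) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform of a time series.

    FFT-accelerated: the transform row at scale ``s`` equals the convolution
    of the signal with the sampled Morlet kernel
    ``(dt/s) * pi^(-1/4) * exp(i*omega0*u/s) * exp(-u^2/(2 s^2))``,
    evaluated in the frequency domain with enough zero padding that the
    circular convolution is exact (to the kernel's Gaussian tail, < 1e-12).
    The amplitude normalization (1/s rather than 1/sqrt(s)) makes the response
    to a unit sinusoid the same at every scale, so the modulus ridge of a pure
    tone sits at the grid frequency nearest the tone.

    Raises
    ------
    ValueError
        If the input contains NaN, a grid frequency exceeds the Nyquist
        frequency, or the series is shorter than two periods of the lowest
        analysis frequency, or omega0 < 5 (admissibility of the
        ``f = omega0 / (2 pi s)`` approximation).
    """
    x = series.values
    if np.isnan(x).any():
        raise ValueError("morlet_wt: input series contains NaN")
    if omega0 < 5:
        raise ValueError(f"omega0 must be >= 5 for the pseudo-frequency mapping, got {omega0}")
    nyq = series.rate_hz / 2.0
    fmax = float(grid.frequencies_hz[-1])
    if fmax > nyq + 1e-12:
        raise ValueError(
            f"grid frequency {fmax:g} Hz exceeds the Nyquist frequency {nyq:g} Hz "
            f"of the input series (rate {series.rate_hz:g} Hz)"
        )
    fmin = float(grid.frequencies_hz[0])
    if series.duration_s < 2.0 / fmin:
        raise ValueError(
            f"series of {series.duration_s:.3g} s does not cover two periods of the "
            f"lowest analysis frequency {fmin:g} Hz"
        )

    n = x.size
    dt = series.dt
    scales = _scales_s(grid, omega0)
    pad = int(np.ceil(8.0 * scales.max() / dt))
    n_fft = next_fast_len(n + 2 * pad)
    xhat = fft(x, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=dt)

    # psi_hat(s*omega) for the sampled kernel above; real-valued Gaussian
    arg = scales[:, None] * omega[None, :] - omega0
    psi_hat = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi) * np.exp(-0.5 * arg ** 2)
    coeffs = ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]

    return WaveletSpectrum(
        coefficients=np.ascontiguousarray(coeffs),
        grid=grid,
        times=series.times,
        coi_mask=_coi_mask(n, dt, scales),
        source_rate_hz=series.rate_hz,
        omega0=omega0,
    )


def _bartlett_smooth(z: np.ndarray, window: int) -> np.ndarray:
    """Triangular (Bartlett) moving average along the time axis."""
    if window <= 1:
        return z
    w = np.bartlett(window + 2)[1:-1]  # strictly positive interior taps
    w = w / w.sum()
    out = np.empty_like(z)
    for i in range(z.shape[0]):
        out[i] = np.convolve(z[i], w, mode="same")
    return out


def cross_wavelet(
    wt_a: WaveletSpectrum,
    wt_b: WaveletSpectrum,
    smoothing_window_s: float = 1.0,
    phase_from_smoothed: bool = True,
) -> CrossWaveletResult:
    """Cross-wavelet transform of two wavelet spectra on identical grids.

    The raw cross coefficient is ``W_a * conj(W_b)``. It is smoothed along
    time with a Bartlett window of ``smoothing_window_s`` seconds; energy is
    the squared modulus of the smoothed coefficients, and phase is by default
    also taken from the smoothed coefficients (set ``phase_from_smoothed=False``
    for the raw pointwise phase). The COI is the union of the input COIs.
    """
    if len(wt_a.grid) != len(wt_b.grid) or not np.allclose(
        wt_a.grid.frequencies_hz, wt_b.grid.frequencies_hz
    ):
        raise ValueError("cross_wavelet requires identical frequency grids")
    if wt_a.times.size != wt_b.times.size or not np.allclose(wt_a.times, wt_b.times):
        raise ValueError("cross_wavelet requires identical time axes")
    if wt_a.source_rate_hz != wt_b.source_rate_hz:
        raise ValueError("cross_wavelet requires identical source rates")

    raw = wt_a.coefficients * np.conj(wt_b.coefficients)
    window = max(1, int(round(smoothing_window_s * wt_a.source_rate_hz)))
    smoothed = _bartlett_smooth(raw, window)
    phase_src = smoothed if phase_from_smoothed else raw
    return CrossWaveletResult(
        cross_coefficients=smoothed,
        energy=np.abs(smoothed) ** 2,
        phase=np.angle(phase_src),
        grid=wt_a.grid,
        times=wt_a.times,
        coi_mask=wt_a.coi_mask | wt_b.coi_mask,
        source_rate_hz=wt_a.source_rate_hz,
        smoothing_window_s=smoothing_window_s,
        phase_from_smoothed=phase_from_smoothed,
    )


def _band_rows(grid: FrequencyGrid, band: FrequencyBand) -> np.ndarray:
    rows = np.flatnonzero(
        (grid.frequencies_hz >= band.low_hz) & (grid.frequencies_hz < band.high_hz)
    )
    if rows.size == 0:
        raise ValueError(
            f"band [{band.low_hz:g}, {band.high_hz:g}) Hz contains no grid frequencies"
        )
    return rows


def band_energy(
    result: CrossWaveletResult | WaveletSpectrum,
    band: FrequencyBand,
    coi_policy: str = "keep",
) -> TimeSeries:
    """Per-time mean energy over the grid rows inside ``[low_hz, high_hz)``.

    ``coi_policy="keep"`` (default) averages over all rows;
    ``coi_policy="mask"`` excludes edge-affected cells and emits NaN for time
    columns where every band row is inside the COI.
    """
    if coi_policy not in ("keep", "mask"):
        raise ValueError(f"coi_policy must be 'keep' or 'mask', got {coi_policy!r}")
    rows = _band_rows(result.grid, band)
    energy = result.energy[rows]
    if coi_policy == "keep":
        vals = energy.mean(axis=0)
    else:
        ok = ~result.coi_mask[rows]
        cnt = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            vals = np.where(cnt > 0, (energy * ok).sum(axis=0) / np.maximum(cnt, 1), np.nan)
    rate = result.source_rate_hz
    return TimeSeries(vals, rate, t0=float(result.times[0]))


def band_phase(result: CrossWaveletResult, band: FrequencyBand) -> TimeSeries:
    """Energy-weighted circular mean phase over a band, in (-pi, pi].

    Time columns where every band row is COI-masked yield NaN (missing), not 0.
    """
    rows = _band_rows(result.grid, band)
    w = result.energy[rows]
    ph = result.phase[rows]
    z = (w * np.exp(1j * ph)).sum(axis=0)
    vals = np.angle(z)
    all_masked = result.coi_mask[rows].all(axis=0)
    vals = np.where(all_masked, np.nan, vals)
    # zero total weight has undefined direction; report missing there too
    vals = np.where(np.abs(z) == 0, np.nan, vals)
    return TimeSeries(vals, result.source_rate_hz, t0=float(result.times[0]))


def summed_wt_energy(
    wt_a: WaveletSpectrum, wt_b: WaveletSpectrum, band: FrequencyBand
) -> TimeSeries:
    """Band energy of each individual transform, summed across the duo.

    Captures moments when both performers move periodically regardless of
    whether their periods are related (the cross transform responds only to
    shared periodicity).
    """
    ea = band_energy(wt_a, band)
    eb = band_energy(wt_b, band)
    if len(ea) != len(eb):
        raise ValueError("summed_wt_energy requires equal-length spectra")
    return TimeSeries(ea.values + eb.values, ea.rate_hz, t0=ea.t0)


def cooccurrence_density(
    wt_a: WaveletSpectrum,
    wt_b: WaveletSpectrum,
    bands7: list[FrequencyBand] | None = None,
) -> np.ndarray:
    """Joint density of the two performers' momentary dominant frequency bands.

    For each time column, each performer's dominant frequency is the grid row
    with maximum WT energy (ties resolve to the lowest frequency); the pair of
    bands containing the two dominant frequencies indexes a cell of the
    returned matrix. Counts are accumulated over time and normalized to sum 1.
    Rows index performer a, columns performer b, in band order.
    """
    if bands7 is None:
        bands7 = cooccurrence_bands()
    if wt_a.coefficients.shape != wt_b.coefficients.shape:
        raise ValueError("spectra must share one shape")
    freqs = wt_a.grid.frequencies_hz
    # map every grid row to its band (bands must jointly cover the grid)
    row_band = np.full(freqs.size, -1, dtype=int)
    for bi, band in enumerate(bands7):
        sel = (freqs >= band.low_hz) & (freqs < band.high_hz)
        if (row_band[sel] != -1).any():
            raise ValueError("co-occurrence bands overlap")
        row_band[sel] = bi
    if (row_band == -1).any():
        raise ValueError("co-occurrence bands do not cover the frequency grid")

    dom_a = row_band[np.argmax(wt_a.energy, axis=0)]
    dom_b = row_band[np.argmax(wt_b.energy, axis=0)]
    k = len(bands7)
    counts = np.zeros((k, k))
    np.add.at(counts, (dom_a, dom_b), 1.0)
    return counts / counts.sum()


def amplitude_profile(
    spectra: list[WaveletSpectrum],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and s.d. across spectra of each spectrum's time-mean amplitude.

    Returns ``(frequencies_hz, mean, sd)``. All spectra must share a grid.
    """
    if not spectra:
        raise ValueError("amplitude_profile requires at least one spectrum")
    freqs = spectra[0].grid.frequencies_hz
    profiles = []
    for sp in spectra:
        if not np.allclose(sp.grid.frequencies_hz, freqs):
            raise ValueError("all spectra must share one frequency grid")
        profiles.append(sp.amplitude.mean(axis=1))
    arr = np.asarray(profiles)
    return freqs, arr.mean(axis=0), arr.std(axis=0)


def save_spectrum(path: str, spectrum: WaveletSpectrum, **metadata) -> None:
    """Columnar archive (npz) plus a JSON metadata block."""
    meta = {
        "omega0": spectrum.omega0,
        "source_rate_hz": spectrum.source_rate_hz,
        "spacing": spectrum.grid.spacing,
        "voices_per_octave": spectrum.grid.voices_per_octave,
        **metadata,
    }
    np.savez(
        path,
        frequencies_hz=spectrum.grid.frequencies_hz,
        times=spectrum.times,
        real=spectrum.coefficients.real,
        imag=spectrum.coefficients.imag,
        coi_mask=spectrum.coi_mask,
        metadata_json=np.array(json.dumps(meta)),
    )


def load_spectrum(path: str) -> WaveletSpectrum:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["metadata_json"]))
        grid = FrequencyGrid(
            z["frequencies_hz"],
            spacing=meta.get("spacing", "log"),
            voices_per_octave=meta.get("voices_per_octave"),
        )
        return WaveletSpectrum(
            coefficients=z["real"] + 1j * z["imag"],
            grid=grid,
            times=z["times"],
            coi_mask=z["coi_mask"].astype(bool),
            source_rate_hz=float(meta["source_rate_hz"]),
            omega0=float(meta["omega0"]),
        )
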