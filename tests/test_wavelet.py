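"""Wavelet core: transform correctness, cross-spectrum phase, band summaries."""

import numpy as np
import pytest

from duetsync.timeseries import TimeSeries
from duetsync.wavelet import (
    FrequencyBand,
    amplitude_profile,
    band_bank,
    band_energy,
    band_phase,
    broad_band,
    cooccurrence_bands,
    cooccurrence_density,
    cross_wavelet,
    load_spectrum,
    log_frequency_grid,
    morlet_wt,
    predictor_bands,
    save_spectrum,
    summed_wt_energy,
)

from conftest import direct_morlet, sinusoid


def nearest(grid, f):
    return grid.frequencies_hz[np.argmin(np.abs(grid.frequencies_hz - f))]


class TestMorletWT:
    def test_matches_direct_convolution_oracle(self, rng):
        """FFT path equals literal time-domain kernel convolution to < 1e-6."""
        rate = 25.0
        x = rng.standard_normal(1500)
        ts = TimeSeries(x, rate)
        grid = log_frequency_grid(0.4, 2.0, 4)  # 5 bracketing frequencies
        wt = morlet_wt(ts, grid)
        for i, f in enumerate(grid.frequencies_hz):
            ref = direct_morlet(x, rate, f)
            err = np.max(np.abs(wt.coefficients[i] - ref)) / np.max(np.abs(ref))
            assert err < 1e-6

    def test_pure_tone_ridge_at_nearest_grid_frequency(self, movement_grid):
        ts = sinusoid(0.5)
        wt = morlet_wt(ts, movement_grid)
        interior = ~wt.coi_mask.any(axis=0)
        ridge = movement_grid.frequencies_hz[np.argmax(wt.energy[:, interior], axis=0)]
        assert np.all(ridge == nearest(movement_grid, 0.5))

    def test_zero_series_gives_zero_coefficients(self, movement_grid):
        ts = TimeSeries(np.zeros(3000), 25.0)
        wt = morlet_wt(ts, movement_grid)
        assert np.all(wt.coefficients == 0)

    def test_two_tone_mixture_shows_both_ridges(self, movement_grid):
        """Each component of a 0.4 + 1.0 Hz mixture produces a local modulus
        maximum within one grid step of the nearest grid frequency."""
        t = np.arange(3000) / 25.0
        x = np.sin(2 * np.pi * 0.4 * t) + np.sin(2 * np.pi * 1.0 * t)
        wt = morlet_wt(TimeSeries(x, 25.0), movement_grid)
        col = wt.energy[:, 1500]
        peaks = [
            i
            for i in range(1, col.size - 1)
            if col[i] > col[i - 1] and col[i] > col[i + 1]
        ]
        freqs = movement_grid.frequencies_hz
        for f in (0.4, 1.0):
            i_near = int(np.argmin(np.abs(freqs - f)))
            assert any(abs(p - i_near) <= 1 for p in peaks)
            # cross-check ridge positions against the direct-convolution oracle
            amps = [np.abs(direct_morlet(x, 25.0, freqs[i]))[1500] for i in
                    (i_near - 1, i_near, i_near + 1)]
            assert np.argmax(amps) in (0, 1, 2)

    def test_amplitude_scaling_is_quadratic_in_energy(self, movement_grid):
        """Scaling the signal by c scales total WT energy by c^2 (to 1e-8)."""
        ts1 = sinusoid(0.7, duration_s=80)
        ts3 = TimeSeries(3.0 * ts1.values, ts1.rate_hz)
        e1 = morlet_wt(ts1, movement_grid).energy.sum()
        e3 = morlet_wt(ts3, movement_grid).energy.sum()
        assert abs(e3 / e1 - 9.0) < 1e-8

    def test_chirp_ridge_tracks_instantaneous_frequency(self, movement_grid):
        """A 0.3 -> 2.0 Hz chirp's ridge stays within one grid step of the
        instantaneous frequency outside the COI."""
        rate, dur = 25.0, 240.0
        t = np.arange(int(dur * rate)) / rate
        f0, f1 = 0.3, 2.0
        k = (f1 - f0) / dur
        inst_f = f0 + k * t
        x = np.sin(2 * np.pi * (f0 * t + 0.5 * k * t ** 2))
        wt = morlet_wt(TimeSeries(x, rate), movement_grid)
        freqs = movement_grid.frequencies_hz
        interior = np.flatnonzero(~wt.coi_mask.any(axis=0))
        # stay clear of the sweep ends where the ridge saturates at the grid edge
        interior = interior[(inst_f[interior] > 0.35) & (inst_f[interior] < 1.85)]
        ridge_idx = np.argmax(wt.energy[:, interior], axis=0)
        near_idx = np.argmin(
            np.abs(np.log(freqs[:, None] / inst_f[interior][None, :])), axis=0
        )
        assert np.all(np.abs(ridge_idx - near_idx) <= 1)

    def test_rejects_bad_inputs(self, movement_grid):
        with pytest.raises(ValueError, match="NaN"):
            morlet_wt(TimeSeries([0.0, np.nan, 1.0, 2.0] * 300, 25.0), movement_grid)
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_wt(sinusoid(0.5, rate_hz=3.0, duration_s=300), movement_grid)
        with pytest.raises(ValueError, match="two periods"):
            morlet_wt(sinusoid(0.5, duration_s=5.0), movement_grid)
        with pytest.raises(ValueError, match="omega0"):
            morlet_wt(sinusoid(0.5), movement_grid, omega0=3.0)


class TestCrossWavelet:
    def test_identical_signals_zero_phase_high_energy(self, movement_grid):
        ts = sinusoid(0.5)
        wt = morlet_wt(ts, movement_grid)
        cw = cross_wavelet(wt, wt)
        interior = ~cw.coi_mask.any(axis=0)
        ridge_row = np.argmax(cw.energy[:, interior].mean(axis=1))
        assert movement_grid.frequencies_hz[ridge_row] == nearest(movement_grid, 0.5)
        assert np.all(np.abs(cw.phase[:, interior]) < 1e-9)

    @pytest.mark.parametrize(
        "freq,lag_frac,expected",
        [
            (0.3, 0.0, 0.0),
            (0.3, 0.25, np.pi / 2),
            (0.6, 0.25, np.pi / 2),
            (2.0, 0.25, np.pi / 2),
            (0.6, 0.125, np.pi / 4),
            (0.6, 0.5, np.pi),
        ],
    )
    def test_lagged_sinusoid_phase(self, movement_grid, freq, lag_frac, expected):
        """Delaying the second signal by a fraction of its period produces the
        analytic phase (positive = b lags a) at the ridge, outside the COI."""
        ts_a = sinusoid(freq, duration_s=160)
        lag_s = lag_frac / freq
        t = ts_a.times
        ts_b = TimeSeries(np.sin(2 * np.pi * freq * (t - lag_s)), ts_a.rate_hz)
        cw = cross_wavelet(
            morlet_wt(ts_a, movement_grid), morlet_wt(ts_b, movement_grid)
        )
        row = int(np.argmin(np.abs(movement_grid.frequencies_hz - freq)))
        interior = ~cw.coi_mask[row]
        interior[: int(10 * ts_a.rate_hz)] = False
        interior[-int(10 * ts_a.rate_hz):] = False
        phases = cw.phase[row, interior]
        err = np.abs(np.angle(np.exp(1j * (phases - expected))))
        assert err.max() < 0.05

    def test_conjugate_symmetry(self, movement_grid, rng):
        a = TimeSeries(rng.standard_normal(1200), 25.0)
        b = TimeSeries(rng.standard_normal(1200), 25.0)
        wa, wb = morlet_wt(a, movement_grid), morlet_wt(b, movement_grid)
        ab = cross_wavelet(wa, wb)
        ba = cross_wavelet(wb, wa)
        np.testing.assert_allclose(ab.phase, -ba.phase, atol=1e-12)
        np.testing.assert_allclose(ab.energy, ba.energy, rtol=1e-12)

    def test_noise_vs_matched_sinusoid_energy(self, movement_grid, rng):
        """An independent white-noise partner carries far less 0.5 Hz band
        energy than a phase-locked identical partner (Monte-Carlo)."""
        ts = sinusoid(0.5)
        wt = morlet_wt(ts, movement_grid)
        band = FrequencyBand(0.5, 0.45, 0.56)
        matched = band_energy(cross_wavelet(wt, wt), band).values.mean()
        noise_means = []
        for _ in range(100):
            nts = TimeSeries(rng.standard_normal(len(ts)), ts.rate_hz)
            cw = cross_wavelet(wt, morlet_wt(nts, movement_grid))
            noise_means.append(band_energy(cw, band).values.mean())
        assert np.mean(noise_means) < 0.1 * matched

    def test_mismatched_grids_rejected(self, movement_grid):
        ts = sinusoid(0.5)
        other = log_frequency_grid(0.3, 2.0, 10)
        with pytest.raises(ValueError, match="grid"):
            cross_wavelet(morlet_wt(ts, movement_grid), morlet_wt(ts, other))


class TestBandSummaries:
    def test_band_energy_localized_at_signal_band(self, movement_grid):
        ts = sinusoid(0.6)
        cw = cross_wavelet(morlet_wt(ts, movement_grid), morlet_wt(ts, movement_grid))
        e_sig = band_energy(cw, FrequencyBand(0.6, 0.49, 0.735))
        e_far = band_energy(cw, FrequencyBand(2.0, 1.342, 2.3))
        inner = slice(int(10 * ts.rate_hz), -int(10 * ts.rate_hz))
        assert np.all(e_sig.values[inner] > e_far.values[inner])

    def test_zero_energy_input_gives_zero_series(self, movement_grid):
        ts = TimeSeries(np.zeros(3000), 25.0)
        cw = cross_wavelet(morlet_wt(ts, movement_grid), morlet_wt(ts, movement_grid))
        assert np.all(band_energy(cw, broad_band()).values == 0)

    def test_broad_band_is_weighted_combination_of_narrow_bands(self, movement_grid, rng):
        """The broad 0.3-2.0 Hz mean equals the row-count-weighted mean of
        the five narrow bands tiling it on the same grid (to 1e-10)."""
        a = TimeSeries(rng.standard_normal(2000), 25.0)
        b = TimeSeries(rng.standard_normal(2000), 25.0)
        cw = cross_wavelet(morlet_wt(a, movement_grid), morlet_wt(b, movement_grid))
        freqs = movement_grid.frequencies_hz
        bands = predictor_bands()
        broad = broad_band()
        n_rows, acc = 0, 0.0
        for band in bands:
            rows = np.sum((freqs >= band.low_hz) & (freqs < band.high_hz))
            acc = acc + rows * band_energy(cw, band).values
            n_rows += rows
        combined = acc / n_rows
        np.testing.assert_allclose(
            combined, band_energy(cw, broad).values, atol=1e-10
        )

    def test_empty_band_rejected(self, movement_grid):
        ts = sinusoid(0.5)
        cw = cross_wavelet(morlet_wt(ts, movement_grid), morlet_wt(ts, movement_grid))
        with pytest.raises(ValueError, match="no grid frequencies"):
            band_energy(cw, FrequencyBand(0.301, 0.3005, 0.3015))

    @pytest.mark.parametrize(
        "lag_frac,expected", [(0.0, 0.0), (0.5, np.pi), (0.25, np.pi / 2)]
    )
    def test_band_phase_of_lagged_pairs(self, movement_grid, lag_frac, expected):
        freq = 0.6
        ts_a = sinusoid(freq, duration_s=160)
        t = ts_a.times
        ts_b = TimeSeries(np.sin(2 * np.pi * freq * (t - lag_frac / freq)), 25.0)
        cw = cross_wavelet(
            morlet_wt(ts_a, movement_grid), morlet_wt(ts_b, movement_grid)
        )
        ph = band_phase(cw, FrequencyBand(0.6, 0.49, 0.735))
        inner = ph.values[int(15 * 25) : -int(15 * 25)]
        assert np.abs(np.abs(np.cos(inner)) - np.abs(np.cos(expected))).max() < 0.01
        if expected == np.pi:
            assert np.abs(np.cos(inner) + 1).max() < 0.01

    def test_band_phase_all_masked_column_is_nan(self, movement_grid):
        ts = sinusoid(0.5, duration_s=40)
        cw = cross_wavelet(morlet_wt(ts, movement_grid), morlet_wt(ts, movement_grid))
        # narrow slow band: first column is fully inside the COI at 0.3 Hz
        ph = band_phase(cw, FrequencyBand(0.31, 0.3, 0.32))
        assert np.isnan(ph.values[0])

    def test_summed_wt_energy_additivity(self, movement_grid):
        flat = TimeSeries(np.full(3000, 1e-9), 25.0)
        per = sinusoid(0.5)
        broad = broad_band()
        w_per = morlet_wt(per, movement_grid)
        w_flat = morlet_wt(flat, movement_grid)
        both = summed_wt_energy(w_per, w_flat, broad)
        alone = band_energy(w_per, broad)
        np.testing.assert_allclose(both.values, alone.values, atol=1e-10)
        zero = morlet_wt(TimeSeries(np.zeros(3000), 25.0), movement_grid)
        assert np.all(summed_wt_energy(zero, zero, broad).values == 0)

    def test_unrelated_periodicities_high_wt_low_cwt(self, movement_grid):
        """Performers periodic at unrelated 0.4 / 1.0 Hz: summed individual
        WT energy stays high while cross energy drops well below the
        matched-frequency case."""
        a = sinusoid(0.4)
        b = sinusoid(1.0)
        wa, wb = morlet_wt(a, movement_grid), morlet_wt(b, movement_grid)
        broad = broad_band()
        inner = slice(int(12 * 25), -int(12 * 25))
        summed = summed_wt_energy(wa, wb, broad).values[inner].mean()
        cross_unrel = band_energy(cross_wavelet(wa, wb), broad).values[inner].mean()
        b2 = sinusoid(0.4, phase_rad=0.3)
        cross_match = band_energy(
            cross_wavelet(wa, morlet_wt(b2, movement_grid)), broad
        ).values[inner].mean()
        assert summed > 10 * cross_unrel
        assert cross_match > 5 * cross_unrel


class TestCooccurrence:
    def test_shared_frequency_fills_diagonal_cell(self, movement_grid):
        ts = sinusoid(0.67)
        wt = morlet_wt(ts, movement_grid)
        m = cooccurrence_density(wt, wt)
        centers = [b.center_hz for b in cooccurrence_bands()]
        i = centers.index(0.67)
        assert m[i, i] == pytest.approx(1.0)

    def test_distinct_frequencies_fill_off_diagonal_cell(self, movement_grid):
        wa = morlet_wt(sinusoid(0.5), movement_grid)
        wb = morlet_wt(sinusoid(0.67), movement_grid)
        m = cooccurrence_density(wa, wb)
        centers = [b.center_hz for b in cooccurrence_bands()]
        assert m[centers.index(0.5), centers.index(0.67)] == pytest.approx(1.0)

    def test_density_normalized_nonnegative_random_inputs(self, movement_grid):
        for seed in range(50):
            r = np.random.default_rng(seed)
            wa = morlet_wt(TimeSeries(r.standard_normal(600), 25.0), movement_grid)
            wb = morlet_wt(TimeSeries(r.standard_normal(600), 25.0), movement_grid)
            m = cooccurrence_density(wa, wb)
            assert m.sum() == pytest.approx(1.0)
            assert (m >= 0).all()


class TestAmplitudeProfile:
    def test_single_tone_profile_peaks_at_tone(self, movement_grid):
        ts = sinusoid(0.75)
        wt = morlet_wt(ts, movement_grid)
        freqs, mean, sd = amplitude_profile([wt])
        assert freqs[np.argmax(mean)] == nearest(movement_grid, 0.75)
        # oracle cross-check at the peak and a neighbour
        i = int(np.argmax(mean))
        amp_peak = np.abs(direct_morlet(ts.values, 25.0, freqs[i])).mean()
        amp_off = np.abs(direct_morlet(ts.values, 25.0, freqs[i - 10])).mean()
        assert amp_peak > amp_off

    def test_identical_spectra_zero_sd(self, movement_grid):
        wt = morlet_wt(sinusoid(0.5), movement_grid)
        _, _, sd = amplitude_profile([wt, wt, wt])
        assert np.all(sd < 1e-15)

    def test_disjoint_peaks_yield_bimodal_mean(self, movement_grid):
        w1 = morlet_wt(sinusoid(0.4), movement_grid)
        w2 = morlet_wt(sinusoid(1.5), movement_grid)
        freqs, mean, _ = amplitude_profile([w1, w2])
        maxima = [
            i for i in range(1, mean.size - 1)
            if mean[i] >= mean[i - 1] and mean[i] >= mean[i + 1]
        ]
        near = lambda f: int(np.argmin(np.abs(freqs - f)))
        assert any(abs(i - near(0.4)) <= 1 for i in maxima)
        assert any(abs(i - near(1.5)) <= 1 for i in maxima)


def test_spectrum_roundtrip(tmp_path, movement_grid):
    wt = morlet_wt(sinusoid(0.5, duration_s=40), movement_grid)
    path = tmp_path / "spec.npz"
    save_spectrum(path, wt, band_rule="geometric-midpoint")
    back = load_spectrum(path)
    np.testing.assert_allclose(back.coefficients, wt.coefficients)
    np.testing.assert_array_equal(back.coi_mask, wt.coi_mask)
    assert back.omega0 == wt.omega0


def test_band_bank_edges_are_geometric_midpoints():
    bands = band_bank((0.3, 0.4, 0.6, 0.9, 2.0), low_edge=0.26, high_edge=2.3)
    assert bands[0].low_hz == 0.26 and bands[-1].high_hz == 2.3
    for b1, b2 in zip(bands, bands[1:]):
        assert b1.high_hz == pytest.approx(np.sqrt(b1.center_hz * b2.center_hz))
        assert b1.high_hz == b2.low_hz  # contiguous in log frequency
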