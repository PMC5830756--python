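"""Reproducible validation benchmarks for the whole pipeline.

Each function here recomputes one headline property of the method from
scratch on simulated data: transform correctness against an independent
time-domain oracle, analytic phase recovery, closed-form agreement values,
bout classification on ground-truth coupled dyads, the interaction-capture
advantage of tree models, end-to-end video frequency recovery, and the
pulsed/non-pulsed audio contrast. The same entry points back the acceptance
script and the heavyweight end of the test suite.
"""

from __future__ import annotations

import numpy as np

from .annotations import cohens_kappa
from .audio import extract_envelope, pulse_clarity_simple
from .classify import fit_predict, split_train_eval
from .movement import VideoROI, preprocess, track_barycentre
from .predictors import (
    EIGHT_PREDICTOR_SET,
    ONE_PREDICTOR_SET,
    DuoRecording,
    build_table,
)
from .simulate import (
    nonpulsed_config,
    pulsed_config,
    render_blob_video,
    simulate_audio,
    simulate_dyad,
)
from .timeseries import TimeSeries
from .wavelet import (
    band_phase,
    broad_band,
    cross_wavelet,
    log_frequency_grid,
    morlet_wt,
    FrequencyBand,
)

__all__ = [
    "direct_morlet_oracle",
    "wavelet_oracle_error",
    "phase_recovery_error",
    "kappa_closed_form_values",
    "simulate_duo_dataset",
    "bout_recovery_aucs",
    "xor_auc_gap",
    "video_frequency_recovery",
    "pulse_clarity_contrast",
]


def direct_morlet_oracle(
    x: np.ndarray, rate_hz: float, freq_hz: float, omega0: float = 6.0
) -> np.ndarray:
    """Literal time-domain convolution with the sampled Morlet kernel.

    Kept deliberately naive and separate from the FFT implementation so it
    can serve as its independent reference.
    """
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


def wavelet_oracle_error(seed: int = 0, n: int = 2000, n_freqs: int = 5) -> float:
    """Max relative error of the FFT transform vs the direct oracle."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    rate = 25.0
    grid = log_frequency_grid(0.4, 2.0, n_freqs - 1)
    wt = morlet_wt(TimeSeries(x, rate), grid)
    worst = 0.0
    for i, f in enumerate(grid.frequencies_hz):
        ref = direct_morlet_oracle(x, rate, f)
        err = np.max(np.abs(wt.coefficients[i] - ref)) / np.max(np.abs(ref))
        worst = max(worst, float(err))
    return worst


def phase_recovery_error(
    freqs=(0.3, 0.6, 2.0), lag_fracs=(0.0, 0.125, 0.25, 0.5)
) -> float:
    """Worst absolute error (rad) of cross-wavelet phase vs the analytic lag.

    For each frequency and lag (as a fraction of the period), compares the
    ridge-band phase of two lagged sinusoids with the analytic value
    ``2 pi lag_frac``, outside the COI and clear of smoothing edges.
    """
    rate = 25.0
    grid = log_frequency_grid(0.25, 2.2, 20)
    worst = 0.0
    for f in freqs:
        ts_a = TimeSeries(
            np.sin(2 * np.pi * f * np.arange(int(160 * rate)) / rate), rate
        )
        wt_a = morlet_wt(ts_a, grid)
        for frac in lag_fracs:
            lag_s = frac / f
            t = ts_a.times
            ts_b = TimeSeries(np.sin(2 * np.pi * f * (t - lag_s)), rate)
            cw = cross_wavelet(wt_a, morlet_wt(ts_b, grid))
            band = FrequencyBand(f, f / 1.1, f * 1.1)
            ph = band_phase(cw, band).values
            margin = int(12 * rate)
            inner = ph[margin:-margin]
            expected = 2 * np.pi * frac
            err = np.abs(np.angle(np.exp(1j * (inner - expected)))).max()
            worst = max(worst, float(err))
    return worst


def kappa_closed_form_values() -> dict[str, float]:
    """Cohen's kappa on hand-built coincidence tables.

    The 40/10/10/40 table has p_o = 0.8 and p_e = 0.5, hence kappa = 0.6;
    a series against itself gives kappa 1; independent fair coins give 0.
    """
    a = TimeSeries(np.r_[np.ones(50), np.zeros(50)], 25.0)
    b = TimeSeries(
        np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)], 25.0
    )
    rng = np.random.default_rng(0)
    x = TimeSeries(rng.integers(0, 2, 100_000).astype(float), 25.0)
    y = TimeSeries(rng.integers(0, 2, 100_000).astype(float), 25.0)
    return {
        "kappa_40_10_10_40": cohens_kappa(a, b).kappa,
        "kappa_identical": cohens_kappa(a, a).kappa,
        "kappa_null": cohens_kappa(x, y).kappa,
    }


def simulate_duo_dataset(
    n_duos: int = 20,
    duration_s: float = 120.0,
    coupling: float = 1.0,
    seed: int = 0,
):
    """Predictor table for a corpus of simulated duos (movement predictors)."""
    duos = []
    for k in range(n_duos):
        cfg = nonpulsed_config(
            duration_s=duration_s, seed=seed * 1009 + k, coupling=coupling
        )
        d = simulate_dyad(cfg)
        duos.append(
            DuoRecording(
                rho_a=d.rho_a, rho_b=d.rho_b, bouts=d.truth,
                qom_a=d.qom_a, qom_b=d.qom_b, recording_id=f"sim{k}",
            )
        )
    return build_table(duos)


def bout_recovery_aucs(table, seed: int = 0, n_folds: int = 5) -> dict[str, float]:
    """Held-out AUC of the 1-predictor logistic and 8-predictor forest.

    Recordings (not frames) are split into ``n_folds`` groups and each fold's
    AUC is measured on recordings the model never saw; the mean over folds is
    returned. Grouping matters: temporally adjacent frames are strongly
    autocorrelated, so a frame-level split lets a flexible model score high
    by interpolating its own training neighbourhood even when movement and
    labels are causally unrelated. The grouped split is what makes the
    zero-coupling null land at chance level.
    """
    rng = np.random.default_rng(seed)
    rec_ids = table["recording_id"].unique()
    order = rng.permutation(rec_ids)
    folds = np.array_split(order, n_folds)
    aucs = {"auc_logistic_1pred": [], "auc_rf_8pred": []}
    for fold in folds:
        held = table["recording_id"].isin(fold)
        train, eval_set = table[~held], table[held]
        logistic = fit_predict(
            train, eval_set, "logistic", ONE_PREDICTOR_SET, cv=None, seed=seed
        )
        forest = fit_predict(
            train, eval_set, "random_forest", EIGHT_PREDICTOR_SET, cv=None, seed=seed
        )
        aucs["auc_logistic_1pred"].append(logistic.auc)
        aucs["auc_rf_8pred"].append(forest.auc)
    return {k: float(np.mean(v)) for k, v in aucs.items()}


def xor_auc_gap(seed: int = 0, n: int = 3000) -> float:
    """RF-minus-logistic held-out AUC gap on XOR-structured two-predictor data."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    u = rng.uniform(-1, 1, n)
    v = rng.uniform(-1, 1, n)
    t = pd.DataFrame(
        {
            "mov_cwt_energy_broad": u,
            "mov_cwt_energy_0.6": v,
            "label": (u * v > 0).astype(int),
            "recording_id": "xor",
            "time_s": np.arange(n) / 5.0,
        }
    )
    tr, ev = split_train_eval(t, seed=seed)
    preds = ["mov_cwt_energy_broad", "mov_cwt_energy_0.6"]
    lo = fit_predict(tr, ev, "logistic", preds, cv=None, seed=seed)
    rf = fit_predict(tr, ev, "random_forest", preds, ntree=200, cv=None, seed=seed)
    return float(rf.auc - lo.auc)


def video_frequency_recovery(
    n_runs: int = 40, duration_s: float = 30.0, seed: int = 0
) -> float:
    """Fraction of runs where render -> track -> transform recovers the
    generator oscillation frequency within one grid step."""
    from .movement import MovementTrace

    rng = np.random.default_rng(seed)
    rate = 25.0
    grid = log_frequency_grid(0.3, 2.0, 20)
    hits = 0
    for _ in range(n_runs):
        f = float(np.exp(rng.uniform(np.log(0.35), np.log(1.9))))
        t = np.arange(int(duration_s * rate)) / rate
        amp = rng.uniform(6, 12)
        x = 40 + amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        x = x + rng.normal(0, 0.3, t.size) + 0.05 * t
        y = 30 + 0.4 * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        frames = render_blob_video(
            MovementTrace(x, y, rate), frame_size=(60, 80), blob_radius=4
        )
        trace = track_barycentre(frames, VideoROI(0, 0, 80, 60))
        rho = preprocess(trace)
        wt = morlet_wt(rho.rho, grid)
        interior = ~wt.coi_mask.any(axis=0)
        ridge = grid.frequencies_hz[
            np.argmax(wt.energy[:, interior].mean(axis=1))
        ]
        if abs(np.log2(ridge / f)) <= 1.01 / 20:
            hits += 1
    return hits / n_runs


def pulse_clarity_contrast(n_pairs: int = 30, seed: int = 0) -> float:
    """Fraction of paired seeds where the pulsed (click-train) preset scores
    higher pulse clarity than the non-pulsed (sparse-event) preset."""
    wins = 0
    for k in range(n_pairs):
        s = seed * 977 + k
        p, sr = simulate_audio(pulsed_config(duration_s=30, seed=s))
        n, _ = simulate_audio(nonpulsed_config(duration_s=30, seed=s))
        cp = np.median(pulse_clarity_simple(extract_envelope(p, sr)).values)
        cn = np.median(pulse_clarity_simple(extract_envelope(n, sr)).values)
        wins += int(cp > cn)
    return wins / n_pairs
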