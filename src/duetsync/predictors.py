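"""Assembly of the 12-predictor frame-wise feature table.

Each retained video frame of each duo recording becomes one row with the
twelve coordination predictors:

====  ========================  ===========================================
 #    column                    meaning
====  ========================  ===========================================
 1    mov_cwt_energy_broad      cross-wavelet energy, 0.3-2.0 Hz
 2    mov_cwt_phase             cross-wavelet phase (lead/lag), 0.3-2.0 Hz
 3-7  mov_cwt_energy_{c}        cross-wavelet energy in the narrow band
                                centred at c in {0.3, 0.4, 0.6, 0.9, 2.0} Hz
 8    mov_wt_energy_any         per-performer wavelet energy, summed in the
                                duo (periodic movement at *any* frequency)
 9    movement_quantity         summed frame-differencing quantity of motion
 10   audio_rms                 RMS of the audio envelope
 11   audio_wt_energy_broad     wavelet energy of the envelope, 0.25-10 Hz
 12   audio_pulse_clarity       simplified pulse clarity of the envelope
====  ========================  ===========================================

plus ``label`` (1 inside a consensus interaction bout), ``recording_id`` and
``time_s``. The first and last 5 s of every recording are trimmed (annotation
and wavelet edge artefacts), frames are decimated by taking every 5th, and
feature columns are z-scored over the assembled set as a whole.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import BoutSet, IntervalTier, binarize
from .audio import audio_rms, audio_wt_energy, pulse_clarity_simple
from .timeseries import RadialSignal, TimeSeries
from .wavelet import (
    FrequencyBand,
    band_energy,
    band_phase,
    broad_band,
    cross_wavelet,
    log_frequency_grid,
    morlet_wt,
    predictor_bands,
    summed_wt_energy,
)

__all__ = [
    "DuoRecording",
    "FEATURE_COLUMNS",
    "MOVEMENT_FEATURES",
    "AUDIO_FEATURES",
    "EIGHT_PREDICTOR_SET",
    "FIVE_PREDICTOR_SET",
    "ONE_PREDICTOR_SET",
    "build_table",
    "write_table",
    "read_table",
]

MOVEMENT_FEATURES = [
    "mov_cwt_energy_broad",
    "mov_cwt_phase",
    "mov_cwt_energy_0.3",
    "mov_cwt_energy_0.4",
    "mov_cwt_energy_0.6",
    "mov_cwt_energy_0.9",
    "mov_cwt_energy_2.0",
    "mov_wt_energy_any",
    "movement_quantity",
]
AUDIO_FEATURES = ["audio_rms", "audio_wt_energy_broad", "audio_pulse_clarity"]
FEATURE_COLUMNS = MOVEMENT_FEATURES + AUDIO_FEATURES

#: Screening survivors: all features except phase and the three audio ones.
EIGHT_PREDICTOR_SET = [c for c in MOVEMENT_FEATURES if c != "mov_cwt_phase"]
#: Features that beat the combined-dataset baseline in the screening stage.
FIVE_PREDICTOR_SET = [
    "mov_cwt_energy_broad",
    "mov_cwt_energy_0.6",
    "mov_cwt_energy_2.0",
    "mov_cwt_energy_0.9",
    "movement_quantity",
]
ONE_PREDICTOR_SET = ["mov_cwt_energy_broad"]


@dataclass
class DuoRecording:
    """Aligned per-duo inputs for table assembly.

    All movement-side signals must share the video frame rate and duration
    (within one frame). ``qom_a/qom_b`` and ``envelope`` may be None; absent
    audio simply leaves the audio columns out (movement-only mode).
    """

    rho_a: RadialSignal
    rho_b: RadialSignal
    bouts: BoutSet
    qom_a: TimeSeries | None = None
    qom_b: TimeSeries | None = None
    envelope: TimeSeries | None = None
    recording_id: str = ""


def _check_duration(duo: DuoRecording) -> None:
    rate = duo.rho_a.rho.rate_hz
    n_a, n_b = len(duo.rho_a.rho), len(duo.rho_b.rho)
    if duo.rho_b.rho.rate_hz != rate:
        raise ValueError(f"{duo.recording_id}: radial signals have different rates")
    if abs(n_a - n_b) > 1:
        raise ValueError(
            f"{duo.recording_id}: signal durations differ by more than one frame"
        )
    for q in (duo.qom_a, duo.qom_b):
        if q is not None and abs(len(q) - n_a) > 1:
            raise ValueError(f"{duo.recording_id}: QoM duration mismatch")


def build_table(
    duos: list[DuoRecording],
    bands: list[FrequencyBand] | None = None,
    trim_s: float = 5.0,
    downsample_factor: int = 5,
    voices_per_octave: int = 20,
    omega0: float = 6.0,
    zscore: bool = True,
    per_recording_zscore: bool = False,
    coi_policy: str = "keep",
) -> pd.DataFrame:
    """Assemble the frame-wise predictor table for a set of duo recordings.

    Movement predictors come from the Morlet WT/CWT of the two radial
    signals; audio predictors are computed on the 100 Hz envelope and
    linearly resampled onto the video frame grid; labels come from binarizing
    the consensus bout set. Per recording the first/last ``trim_s`` seconds
    are dropped and frames decimated by ``downsample_factor`` (plain
    subsampling — the features are slow band energies, already effectively
    low-passed by the wavelet). Feature columns are then z-scored over the
    assembled rows (jointly by default; ``per_recording_zscore=True``
    standardizes each recording separately).

    Returns a DataFrame whose ``attrs["meta"]`` records the analysis
    parameters and the z-score means/sds needed to invert the scaling.
    Rebuilding from identical inputs is bit-identical.
    """
    if not duos:
        raise ValueError("build_table requires at least one recording")
    bands = bands if bands is not None else predictor_bands()
    broad = broad_band()
    frames = []
    have_audio = all(d.envelope is not None for d in duos)
    if any(d.envelope is not None for d in duos) and not have_audio:
        raise ValueError("either all recordings or none must carry audio")
    have_qom = all(d.qom_a is not None and d.qom_b is not None for d in duos)
    if any(d.qom_a is not None for d in duos) and not have_qom:
        raise ValueError("either all recordings or none must carry quantity of motion")

    for duo in duos:
        _check_duration(duo)
        rho_a, rho_b = duo.rho_a.rho, duo.rho_b.rho
        n = min(len(rho_a), len(rho_b))
        rate = rho_a.rate_hz
        grid = log_frequency_grid(broad.low_hz, 2.0, voices_per_octave)
        ts_a = TimeSeries(rho_a.values[:n], rate)
        ts_b = TimeSeries(rho_b.values[:n], rate)
        wt_a = morlet_wt(ts_a, grid, omega0=omega0)
        wt_b = morlet_wt(ts_b, grid, omega0=omega0)
        cw = cross_wavelet(wt_a, wt_b)

        cols: dict[str, np.ndarray] = {}
        cols["mov_cwt_energy_broad"] = band_energy(cw, broad, coi_policy).values
        cols["mov_cwt_phase"] = band_phase(cw, broad).values
        for band in bands:
            cols[f"mov_cwt_energy_{band.center_hz:.1f}"] = band_energy(
                cw, band, coi_policy
            ).values
        cols["mov_wt_energy_any"] = summed_wt_energy(wt_a, wt_b, broad).values
        if duo.qom_a is not None and duo.qom_b is not None:
            m = min(len(duo.qom_a), len(duo.qom_b), n)
            qsum = duo.qom_a.values[:m] + duo.qom_b.values[:m]
            cols["movement_quantity"] = np.pad(qsum, (0, n - m), mode="edge")

        t_frames = ts_a.times
        if have_audio:
            env = duo.envelope
            rms = audio_rms(env)
            cols["audio_rms"] = np.interp(t_frames, rms.times, rms.values)
            awt = audio_wt_energy(env)
            cols["audio_wt_energy_broad"] = np.interp(t_frames, awt.times, awt.values)
            pc = pulse_clarity_simple(env)
            cols["audio_pulse_clarity"] = np.interp(t_frames, pc.times, pc.values)

        labels = binarize(
            IntervalTier("consensus", list(duo.bouts.intervals)), rate, n / rate
        ).values[:n]

        keep = (t_frames >= trim_s) & (t_frames < n / rate - trim_s)
        idx = np.flatnonzero(keep)[::downsample_factor]
        frame = pd.DataFrame({k: v[idx] for k, v in cols.items()})
        frame["label"] = labels[idx].astype(int)
        frame["recording_id"] = duo.recording_id
        frame["time_s"] = t_frames[idx]
        frames.append(frame)

    table = pd.concat(frames, ignore_index=True)
    feat_cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if table[feat_cols].isna().any().any():
        raise ValueError("assembled table contains NaN feature rows")

    meta = {
        "trim_s": trim_s,
        "downsample_factor": downsample_factor,
        "omega0": omega0,
        "voices_per_octave": voices_per_octave,
        "coi_policy": coi_policy,
        "have_audio": have_audio,
        "have_qom": have_qom,
        "band_edges_hz": [[b.low_hz, b.center_hz, b.high_hz] for b in bands],
        "zscore": {},
    }
    if zscore:
        groups = table.groupby("recording_id").groups.values() if per_recording_zscore else [
            table.index
        ]
        for idx in groups:
            for c in feat_cols:
                mu = float(table.loc[idx, c].mean())
                sd = float(table.loc[idx, c].std(ddof=0))
                table.loc[idx, c] = (table.loc[idx, c] - mu) / sd if sd > 0 else 0.0
                meta["zscore"].setdefault(c, []).append({"mean": mu, "sd": sd})
    table.attrs["meta"] = meta
    return table


def write_table(table: pd.DataFrame, csv_path: str) -> None:
    """CSV with fixed header plus a JSON sidecar of analysis metadata."""
    table.to_csv(csv_path, index=False)
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(table.attrs.get("meta", {}), fh, indent=2)


def read_table(csv_path: str) -> pd.DataFrame:
    table = pd.read_csv(csv_path)
    try:
        with open(str(csv_path) + ".json") as fh:
            table.attrs["meta"] = json.load(fh)
    except FileNotFoundError:
        pass
    return table
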