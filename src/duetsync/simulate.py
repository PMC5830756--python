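"""Synthetic dyads: coupled-oscillator movement, noisy annotators, audio, video.

The generator is the test substrate for the whole pipeline. Each performer is
a noisy sinusoidal oscillator whose frequency wanders slowly (body sway / head
nod regime, 0.3-2 Hz). During a scheduled coordination bout both performers'
frequencies relax toward a shared bout frequency and the second performer's
phase is pulled toward the first's by a Kuramoto-style term
``dphi_B += K * coupling * sin(phi_A - phi_B - lag) * dt``. Crucially, the
coupling strength gates *everything*: with ``coupling = 0`` the bout schedule
has no effect whatsoever on the dynamics, so scheduled "bouts" are
statistically indistinguishable from the rest of the performance (the null
case for the classifier).

Annotators are simulated as noisy observers of the true bout set (Gaussian
onset/offset jitter, bout misses, spurious lone bouts). Audio comes in two
presets mirroring the two performance styles: ``pulsed`` (isochronous click
train, accent every 4 beats, default 132 bpm) and ``nonpulsed`` (sparse
Poisson events at ~0.45 events/s). Blob videos render the traces for
end-to-end tests of the tracking path.

Same (config, seed) always reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .annotations import BoutSet, Interval, IntervalTier
from .movement import MovementTrace, VideoROI
from .timeseries import RadialSignal, TimeSeries

__all__ = [
    "BoutSpec",
    "AnnotatorModel",
    "DyadSimConfig",
    "SimulatedDyad",
    "random_bout_schedule",
    "simulate_dyad",
    "simulate_annotators",
    "render_blob_video",
    "simulate_audio",
    "pulsed_config",
    "nonpulsed_config",
]


@dataclass(frozen=True)
class BoutSpec:
    """One scheduled coordination bout."""

    onset_s: float
    offset_s: float
    shared_freq_hz: float
    coupling: float = 1.0  # in [0, 1]; 0 means no effect at all
    phase_lag_rad: float = 0.0


@dataclass(frozen=True)
class AnnotatorModel:
    """Error model for simulated annotators."""

    onset_jitter_sd_s: float = 0.25
    miss_prob: float = 0.1
    false_alarm_rate_per_min: float = 0.2
    n_annotators: int = 3


@dataclass
class DyadSimConfig:
    """Full parameterization of a simulated duo performance."""

    duration_s: float = 150.0
    rate_hz: float = 25.0
    bout_schedule: list[BoutSpec] = field(default_factory=list)
    solo_freqs_hz: tuple[float, float] = (0.45, 1.0)
    freq_drift_sd: float = 0.03  # Hz per sqrt(s) random walk
    amplitude_px: float = 20.0
    noise_sd: float = 2.0  # additive white noise, px
    drift_px_per_sqrt_s: float = 1.0  # slow positional random walk
    structure_schedule: list[Interval] = field(default_factory=list)
    annotator_model: AnnotatorModel = field(default_factory=AnnotatorModel)
    pulsed: bool = True
    tempo_bpm: float = 132.0
    event_rate_hz: float = 0.45  # non-pulsed sparse event rate
    audio_rate_hz: float = 8000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.bout_schedule:
            if not (0 <= b.onset_s < b.offset_s <= self.duration_s):
                raise ValueError(f"bout {b} outside [0, {self.duration_s}]")
            if not 0.0 <= b.coupling <= 1.0:
                raise ValueError("coupling must lie in [0, 1]")
        sched = sorted(self.bout_schedule, key=lambda b: b.onset_s)
        for a, b in zip(sched, sched[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("bout schedule must be non-overlapping")
        self.bout_schedule = sched


@dataclass
class SimulatedDyad:
    """Everything the downstream pipeline needs about one simulated duo."""

    rho_a: RadialSignal
    rho_b: RadialSignal
    trace_a: MovementTrace
    trace_b: MovementTrace
    qom_a: TimeSeries  # displacement-magnitude proxy for frame-differencing QoM
    qom_b: TimeSeries
    truth: BoutSet
    structure: IntervalTier
    config: DyadSimConfig


def random_bout_schedule(
    duration_s: float,
    rng: np.random.Generator,
    mean_bout_s: float = 10.0,
    mean_gap_s: float = 20.0,
    freq_range_hz: tuple[float, float] = (0.35, 1.8),
    coupling: float = 1.0,
    phase_lag_rad: float = 0.0,
    edge_margin_s: float = 8.0,
) -> list[BoutSpec]:
    """Alternating gap/bout schedule with log-uniform shared frequencies.

    Bout and gap lengths are exponential around their means (bouts floored at
    4 s so they are resolvable at the slowest analysis periods); with the
    default means roughly a third of the performance lies inside bouts,
    matching the label prevalence regime the classifier faces.
    """
    bouts = []
    t = edge_margin_s + rng.exponential(mean_gap_s / 2)
    lo, hi = np.log(freq_range_hz[0]), np.log(freq_range_hz[1])
    while True:
        dur = max(4.0, rng.exponential(mean_bout_s))
        if t + dur > duration_s - edge_margin_s:
            break
        bouts.append(
            BoutSpec(
                onset_s=round(t, 3),
                offset_s=round(t + dur, 3),
                shared_freq_hz=float(np.exp(rng.uniform(lo, hi))),
                coupling=coupling,
                phase_lag_rad=phase_lag_rad,
            )
        )
        t += dur + max(3.0, rng.exponential(mean_gap_s))
    return bouts


def _default_structure(duration_s: float) -> list[Interval]:
    """Alternating joint/solo sections of ~20-40 s."""
    sections = []
    t = 0.0
    kinds = ["joint", "solo"]
    k = 0
    while t < duration_s:
        dur = 35.0 if kinds[k % 2] == "joint" else 20.0
        sections.append(Interval(t, min(t + dur, duration_s), label=kinds[k % 2]))
        t += dur
        k += 1
    return sections


def simulate_dyad(config: DyadSimConfig, seed: int | None = None) -> SimulatedDyad:
    """Simulate one duo: movement traces, radial signals, ground truth.

    Each performer's oscillator phase advances at its momentary frequency;
    frequencies perform a reflected random walk around the solo frequencies.
    Inside a bout, both frequencies relax toward the bout's shared frequency
    and performer B's phase is pulled toward A's (strength = coupling), so
    with full coupling the pair phase-locks within ~1 s. The rendered trace
    is the oscillation plus white noise plus a slow positional random walk,
    around a fixed centre; the radial signal is its detrended, [0, 1]
    normalized radial coordinate (frame-origin pole).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rate = config.rate_hz
    dt = 1.0 / rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) * dt

    # per-sample bout membership and parameters
    in_bout = np.zeros(n, dtype=bool)
    shared_f = np.zeros(n)
    coupling = np.zeros(n)
    lag = np.zeros(n)
    for b in config.bout_schedule:
        sel = (t >= b.onset_s) & (t < b.offset_s)
        in_bout[sel] = True
        shared_f[sel] = b.shared_freq_hz
        coupling[sel] = b.coupling
        lag[sel] = b.phase_lag_rad

    solo = np.asarray(config.solo_freqs_hz, dtype=float)
    f = solo.copy()  # momentary frequencies (A, B)
    phi = rng.uniform(0, 2 * np.pi, size=2)
    K = 3.0  # rad/s phase pull at full coupling; at partial coupling the
    # lock stays loose against the frequency drift, so bout energy grades
    # smoothly with coupling instead of saturating
    relax = 1.5  # 1/s relaxation toward the (coupling-weighted) bout frequency
    freq_lo, freq_hi = 0.25, 2.2

    osc = np.empty((2, n))
    drift_steps = rng.normal(0.0, config.freq_drift_sd * np.sqrt(dt), size=(n, 2))
    amp_mod = 1.0 + 0.2 * np.sin(
        2 * np.pi * rng.uniform(0.01, 0.03, size=2)[None, :] * t[:, None]
        + rng.uniform(0, 2 * np.pi, size=2)[None, :]
    )
    for i in range(n):
        osc[0, i] = np.cos(phi[0])
        osc[1, i] = np.cos(phi[1])
        f = f + drift_steps[i]
        # revert drifting frequencies to the solo baselines with ~2 s time
        # constant, so performers reclaim their own tempo soon after a bout
        f = f + 0.5 * (solo - f) * dt
        if in_bout[i] and coupling[i] > 0:
            c = coupling[i]
            # partial coupling pulls each frequency only part of the way to
            # the shared bout frequency, leaving a residual mismatch
            target = (1.0 - c) * solo + c * shared_f[i]
            f = f + relax * (target - f) * dt
            phi[1] += K * c * np.sin(phi[0] - phi[1] - lag[i]) * dt
        f = np.clip(f, freq_lo, freq_hi)
        phi = phi + 2 * np.pi * f * dt
    osc *= config.amplitude_px * amp_mod.T

    centres = np.array([[260.0, 300.0], [440.0, 300.0]])  # (x, y) per performer
    traces = []
    for p in range(2):
        noise = rng.normal(0.0, config.noise_sd, size=(2, n))
        walk = np.cumsum(
            rng.normal(0.0, config.drift_px_per_sqrt_s * np.sqrt(dt), size=(2, n)), axis=1
        )
        x = centres[p, 0] + osc[p] + noise[0] + walk[0]
        y = centres[p, 1] + 0.35 * osc[p] + noise[1] + walk[1]
        traces.append(MovementTrace(x, y, rate))

    rhos = []
    qoms = []
    for tr in traces:
        r = np.hypot(tr.x, tr.y)
        r = _linear_detrend(r)
        span = r.max() - r.min()
        r = (r - r.min()) / span if span > 0 else np.zeros_like(r)
        rhos.append(RadialSignal(TimeSeries(r, rate)))
        # frame differencing responds to how much of the image changes per
        # frame, which for a rigid mover is its per-frame displacement
        disp = np.hypot(np.diff(tr.x, prepend=tr.x[0]), np.diff(tr.y, prepend=tr.y[0]))
        qoms.append(TimeSeries(disp, rate))

    truth = BoutSet(
        [Interval(b.onset_s, b.offset_s) for b in config.bout_schedule],
        support=config.annotator_model.n_annotators,
        recording_id=f"sim{seed}",
    )
    struct_ivs = config.structure_schedule or _default_structure(config.duration_s)
    structure = IntervalTier("structure", struct_ivs, recording_id=f"sim{seed}")
    return SimulatedDyad(
        rhos[0], rhos[1], traces[0], traces[1], qoms[0], qoms[1], truth, structure, config
    )


def simulate_annotators(
    truth: BoutSet,
    model: AnnotatorModel,
    duration_s: float,
    seed: int = 0,
) -> list[IntervalTier]:
    """Noisy annotator tiers of a true bout set.

    Each annotator independently misses each bout with ``miss_prob``, jitters
    surviving onsets/offsets with Gaussian noise, and inserts spurious bouts
    as a Poisson process (``false_alarm_rate_per_min``) with ~4 s exponential
    durations. Overlapping intervals are merged on tier construction.
    """
    rng = np.random.default_rng(seed)
    tiers = []
    for k in range(model.n_annotators):
        ivs = []
        for iv in truth.intervals:
            if rng.random() < model.miss_prob:
                continue
            on = iv.onset_s + rng.normal(0, model.onset_jitter_sd_s)
            off = iv.offset_s + rng.normal(0, model.onset_jitter_sd_s)
            on = float(np.clip(on, 0, duration_s - 0.2))
            off = float(np.clip(off, on + 0.2, duration_s))
            ivs.append(Interval(on, off, label="interaction"))
        n_fa = rng.poisson(model.false_alarm_rate_per_min * duration_s / 60.0)
        for _ in range(n_fa):
            on = rng.uniform(0, duration_s - 1.0)
            dur = float(np.clip(rng.exponential(4.0), 1.0, 10.0))
            off = min(on + dur, duration_s)
            ivs.append(Interval(on, off, label="interaction"))
        tiers.append(
            IntervalTier(f"ann{k}", ivs, recording_id=truth.recording_id)
        )
    return tiers


def render_blob_video(
    trace_a: MovementTrace,
    trace_b: MovementTrace | None = None,
    frame_size: tuple[int, int] = (120, 160),
    blob_radius: float = 5.0,
) -> np.ndarray:
    """Render traces as white blobs on black, shape (n, height, width), uint8.

    Blob edges are softened over one pixel so sub-pixel positions survive the
    rasterization (the intensity centroid then recovers the trace almost
    exactly).
    """
    traces = [trace_a] + ([trace_b] if trace_b is not None else [])
    n = len(trace_a)
    h, w = frame_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.zeros((n, h, w), dtype=np.uint8)
    for i in range(n):
        img = np.zeros((h, w))
        for tr in traces:
            d = np.hypot(xx - tr.x[i], yy - tr.y[i])
            img = np.maximum(img, np.clip(blob_radius + 0.5 - d, 0.0, 1.0))
        frames[i] = np.round(img * 255).astype(np.uint8)
    return frames


def simulate_audio(
    config: DyadSimConfig, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """Synthesize the duo's joint audio; returns (samples, rate_hz).

    ``pulsed=True``: an isochronous click train at ``tempo_bpm`` with an
    amplitude accent every 4 beats. ``pulsed=False``: sparse Poisson events
    (default ~0.45 events/s) with random pitch and slower decays, i.e. no
    regular beat. Clicks are short exponentially decaying tone bursts.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed + 101)
    sr = config.audio_rate_hz
    n = int(round(config.duration_s * sr))
    out = np.zeros(n)

    def add_click(onset_s: float, amp: float, freq: float, decay_s: float) -> None:
        i0 = int(round(onset_s * sr))
        m = min(int(decay_s * 6 * sr), n - i0)
        if m <= 0:
            return
        u = np.arange(m) / sr
        out[i0 : i0 + m] += amp * np.exp(-u / decay_s) * np.sin(2 * np.pi * freq * u)

    if config.pulsed:
        period = 60.0 / config.tempo_bpm
        beat = 0
        onset = 0.1
        while onset < config.duration_s - 0.1:
            amp = 0.9 if beat % 4 == 0 else 0.6
            add_click(onset, amp, 1000.0, 0.012)
            onset += period
            beat += 1
    else:
        n_events = rng.poisson(config.event_rate_hz * config.duration_s)
        onsets = np.sort(rng.uniform(0.1, config.duration_s - 0.5, size=n_events))
        for onset in onsets:
            add_click(
                float(onset),
                float(rng.uniform(0.3, 0.9)),
                float(rng.uniform(200, 1200)),
                float(rng.uniform(0.05, 0.3)),
            )
    return out, sr


def pulsed_config(duration_s: float = 150.0, seed: int = 0, **kwargs) -> DyadSimConfig:
    """Preset emulating the metrically regular performance style.

    Shorter coordination bouts (median ~4-6 s), faster tempo (132 bpm),
    clicking pulse in the audio.
    """
    rng = np.random.default_rng(seed)
    sched = random_bout_schedule(
        duration_s, rng, mean_bout_s=5.0, mean_gap_s=14.0, **_sched_kwargs(kwargs)
    )
    return DyadSimConfig(
        duration_s=duration_s,
        bout_schedule=sched,
        pulsed=True,
        tempo_bpm=132.0,
        seed=seed,
        **kwargs,
    )


def nonpulsed_config(duration_s: float = 150.0, seed: int = 0, **kwargs) -> DyadSimConfig:
    """Preset emulating the free-improvisation style.

    Longer bouts (median ~11 s), no pulse, sparse audio events (~0.45/s).
    """
    rng = np.random.default_rng(seed)
    sched = random_bout_schedule(
        duration_s, rng, mean_bout_s=11.0, mean_gap_s=22.0, **_sched_kwargs(kwargs)
    )
    return DyadSimConfig(
        duration_s=duration_s,
        bout_schedule=sched,
        pulsed=False,
        tempo_bpm=106.0,
        seed=seed,
        **kwargs,
    )


def _sched_kwargs(kwargs: dict) -> dict:
    return {k: kwargs.pop(k) for k in ("coupling", "phase_lag_rad") if k in kwargs}
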