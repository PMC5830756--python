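"""Interval annotations: data model, alignment, agreement and aggregation.

Bouts of interaction are marked by several annotators as labelled time
intervals (exported from ELAN as tab-delimited tiers). Before computing
inter-rater agreement, each pair of frame-binarized annotation tracks is
aligned with a band-constrained, asymmetric-step dynamic time warp to absorb
small timing discrepancies; agreement is then Cohen's kappa on the aligned
frame labels. The consensus bout set is every time span marked by at least
two annotators, which removes idiosyncratic single-rater bouts.

All intervals are half-open ``[onset_s, offset_s)`` in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency, norm

from .timeseries import TimeSeries

__all__ = [
    "Interval",
    "IntervalTier",
    "BoutSet",
    "AgreementReport",
    "binarize",
    "intervals_from_binary",
    "dtw_align",
    "cohens_kappa",
    "frame_overlap_fraction",
    "aggregate_bouts",
    "onset_position_histogram",
    "chi_square_histograms",
]


@dataclass(frozen=True)
class Interval:
    onset_s: float
    offset_s: float
    label: str = ""
    free_text: str = ""

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(f"interval onset {self.onset_s} must precede offset {self.offset_s}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _merge_overlaps(intervals: list[Interval], context: str) -> list[Interval]:
    out: list[Interval] = []
    merged = False
    for iv in sorted(intervals, key=lambda i: (i.onset_s, i.offset_s)):
        if out and iv.onset_s < out[-1].offset_s:
            prev = out[-1]
            out[-1] = Interval(
                prev.onset_s,
                max(prev.offset_s, iv.offset_s),
                label=prev.label,
                free_text=(prev.free_text + " | " + iv.free_text).strip(" |"),
            )
            merged = True
        else:
            out.append(iv)
    if merged:
        warnings.warn(f"{context}: overlapping intervals merged", stacklevel=3)
    return out


@dataclass
class IntervalTier:
    """One annotator's sorted, non-overlapping labelled intervals."""

    annotator_id: str
    intervals: list[Interval]
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.intervals = _merge_overlaps(list(self.intervals), f"tier {self.annotator_id}")

    def total_duration_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)


@dataclass
class BoutSet:
    """Consensus bouts: sorted, non-overlapping intervals with rater support."""

    intervals: list[Interval]
    support: int = 2
    recording_id: str = ""

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda i: i.onset_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("BoutSet intervals must be non-overlapping")
        self.intervals = ivs

    def total_duration_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)

    def onsets(self) -> np.ndarray:
        return np.array([iv.onset_s for iv in self.intervals])


@dataclass
class AgreementReport:
    """Cohen's kappa with its large-sample z statistic for one rater pair."""

    kappa: float
    z_stat: float
    p_value: float
    n_frames: int
    pair_ids: tuple[str, str] = ("a", "b")
    alignment_params: dict = field(default_factory=dict)


def binarize(tier: IntervalTier, rate_hz: float, duration_s: float) -> TimeSeries:
    """Frame-label track: sample i is 1 iff its timestamp is inside an interval."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    vals = np.zeros(n)
    for iv in tier.intervals:
        vals[(t >= iv.onset_s) & (t < iv.offset_s)] = 1.0
    return TimeSeries(vals, rate_hz)


def intervals_from_binary(series: TimeSeries, min_frames: int = 1) -> list[Interval]:
    """Runs of ones converted back to half-open intervals."""
    v = (series.values > 0.5).astype(int)
    edges = np.diff(np.concatenate([[0], v, [0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    out = []
    for s, e in zip(starts, stops):
        if e - s >= min_frames:
            out.append(
                Interval(series.t0 + s / series.rate_hz, series.t0 + e / series.rate_hz)
            )
    return out


_STEP_J = np.array([1, 0, 2], dtype=np.int8)  # j-decrements for [diag, repeat, skip]


def dtw_align(
    series_a: TimeSeries, series_b: TimeSeries, band_s: float = 2.0
) -> TimeSeries:
    """Warp series_b onto series_a's time axis by asymmetric banded DTW.

    Step pattern (1,0), (1,1), (1,2): the reference index advances one frame
    per step, the warped series may repeat or skip a frame. The warp path is
    monotonic, boundary-anchored, and confined to a Sakoe-Chiba band of
    ``+-band_s`` seconds. ``band_s = 0`` degenerates to the identity (the
    series must then be equally long).
    """
    if series_a.rate_hz != series_b.rate_hz:
        raise ValueError("dtw_align requires equal sampling rates")
    if band_s < 0:
        raise ValueError("band_s must be >= 0")
    a = series_a.values
    b = series_b.values
    na, nb = a.size, b.size
    band = int(round(band_s * series_a.rate_hz))
    if band < abs(na - nb):
        raise ValueError(
            f"band of {band} frames cannot bridge the length difference {abs(na - nb)}"
        )
    if band == 0:
        return TimeSeries(b.copy(), series_b.rate_hz, series_a.t0)

    INF = np.inf
    D = np.full((na, nb), INF)
    step = np.zeros((na, nb), dtype=np.int8)
    j0 = np.maximum(0, np.arange(na) - band)
    j1 = np.minimum(nb - 1, np.arange(na) + band)
    cost0 = np.abs(a[0] - b)
    D[0, j0[0] : j1[0] + 1] = cost0[j0[0] : j1[0] + 1]
    for i in range(1, na):
        lo, hi = j0[i], j1[i]
        js = np.arange(lo, hi + 1)
        prev = D[i - 1]
        c0 = prev[js]  # (1,0): repeat b frame
        c1 = np.where(js - 1 >= 0, prev[np.maximum(js - 1, 0)], INF)  # (1,1): diagonal
        c2 = np.where(js - 2 >= 0, prev[np.maximum(js - 2, 0)], INF)  # (1,2): skip
        # diagonal first so ties resolve to the identity path
        stacked = np.vstack([c1, c0, c2])
        best = np.argmin(stacked, axis=0)
        D[i, lo : hi + 1] = np.abs(a[i] - b[js]) + stacked[best, np.arange(js.size)]
        step[i, lo : hi + 1] = _STEP_J[best]
    if not np.isfinite(D[na - 1, nb - 1]):
        raise ValueError("no warp path reaches the end point inside the band")

    # backtrack from the anchored end point
    path_j = np.empty(na, dtype=int)
    j = nb - 1
    for i in range(na - 1, -1, -1):
        path_j[i] = j
        j -= int(step[i, j])
        j = max(j, 0)
    return TimeSeries(b[path_j], series_b.rate_hz, series_a.t0)


def cohens_kappa(
    a: TimeSeries, b: TimeSeries, pair_ids: tuple[str, str] = ("a", "b"), **alignment_params
) -> AgreementReport:
    """Cohen's kappa on two equal-length binary frame tracks.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 coincidence table; the z
    statistic uses the standard large-sample null variance. Perfect identical
    constant tracks give kappa = 1 by convention.
    """
    if len(a) != len(b):
        raise ValueError("cohens_kappa requires equal-length series")
    x = (a.values > 0.5).astype(int)
    y = (b.values > 0.5).astype(int)
    n = x.size
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    p1x, p0x = (n11 + n10) / n, (n01 + n00) / n
    p1y, p0y = (n11 + n01) / n, (n10 + n00) / n
    pe = p1x * p1y + p0x * p0y
    if pe >= 1.0 - 1e-15:
        kappa = 1.0 if po >= 1.0 - 1e-15 else 0.0
        return AgreementReport(kappa, float("inf") if kappa == 1 else 0.0, 0.0, n,
                               pair_ids, alignment_params)
    kappa = (po - pe) / (1.0 - pe)
    # large-sample variance of kappa under independence (H0)
    marg = p1x * p1y * (p1x + p1y) + p0x * p0y * (p0x + p0y)
    var0 = (pe + pe ** 2 - marg) / (n * (1.0 - pe) ** 2)
    z = kappa / np.sqrt(var0) if var0 > 0 else float("inf")
    p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return AgreementReport(float(kappa), float(z), float(p), n, pair_ids, alignment_params)


def frame_overlap_fraction(tiers: list[IntervalTier], rate_hz: float, duration_s: float) -> float:
    """Fraction of marked frames that at least one other annotator also marked.

    A frame-wise, pairwise-overlap reading of annotation consistency: of all
    (tier, frame) marks, the share whose frame is marked in >= 2 tiers.
    """
    tracks = np.array([binarize(t, rate_hz, duration_s).values for t in tiers])
    marked = tracks.sum(axis=0)
    total = tracks.sum()
    if total == 0:
        return float("nan")
    shared = (tracks * (marked >= 2)).sum()
    return float(shared / total)


def aggregate_bouts(
    tiers: list[IntervalTier],
    rate_hz: float,
    min_raters: int = 2,
    duration_s: float | None = None,
    min_duration_frames: int = 2,
) -> BoutSet:
    """Consensus bouts: spans where at least ``min_raters`` tiers mark interaction.

    Tiers are binarized on a common frame grid, summed pointwise, thresholded
    at ``min_raters`` and converted back to intervals. Aggregated bouts
    shorter than ``min_duration_frames`` video frames are discarded as
    degenerate.
    """
    if not tiers:
        return BoutSet([], support=min_raters)
    if duration_s is None:
        duration_s = max(
            (iv.offset_s for t in tiers for iv in t.intervals), default=0.0
        )
    if duration_s <= 0:
        return BoutSet([], support=min_raters)
    tracks = np.array([binarize(t, rate_hz, duration_s).values for t in tiers])
    if tracks.shape[1] < 2:
        return BoutSet([], support=min_raters, recording_id=tiers[0].recording_id)
    consensus = TimeSeries((tracks.sum(axis=0) >= min_raters).astype(float), rate_hz)
    ivs = intervals_from_binary(consensus, min_frames=min_duration_frames)
    return BoutSet(ivs, support=min_raters, recording_id=tiers[0].recording_id)


def onset_position_histogram(
    bouts: BoutSet, structure: IntervalTier, bin_pct: float = 5.0
) -> tuple[dict[str, np.ndarray], int]:
    """Bout onsets binned by relative position within their structural section.

    Each bout onset is located in its enclosing structure section (half-open);
    its relative position ``(onset - start) / duration`` is binned into
    ``[0, bin_pct) ... [100 - bin_pct, 100]`` percent bins, separately per
    section label. Returns ``(counts per label, n_dropped)`` where dropped
    onsets fell outside every section.
    """
    n_bins = int(round(100.0 / bin_pct))
    counts: dict[str, np.ndarray] = {}
    dropped = 0
    for onset in bouts.onsets():
        section = next(
            (iv for iv in structure.intervals if iv.onset_s <= onset < iv.offset_s), None
        )
        if section is None:
            dropped += 1
            continue
        rel = (onset - section.onset_s) / section.duration_s * 100.0
        b = min(int(rel // bin_pct), n_bins - 1)
        counts.setdefault(section.label, np.zeros(n_bins, dtype=int))[b] += 1
    return counts, dropped


def chi_square_histograms(h1, h2) -> tuple[float, int, float]:
    """Two-sample chi-square homogeneity test over histogram bins.

    Bins where both histograms are zero are merged out (they carry no
    information and would break the expected-count denominator). No
    continuity correction.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have identical binning")
    keep = (h1 + h2) > 0
    table = np.vstack([h1[keep], h2[keep]])
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return 0.0, 0, 1.0
    if np.array_equal(table[0], table[1]):
        return 0.0, int(table.shape[1] - 1), 1.0
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
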