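"""Video-based movement extraction: barycentre tracking, quantity of motion,
and preprocessing of traces into the radial signal the wavelet bank consumes.

The performer's gross upper-body motion is summarized per frame by the
barycentre (intensity-weighted centroid) of a user-drawn region of interest
(ROI), yielding an (x, y) trace at the video frame rate. An overall quantity
of motion (QoM) is extracted from the same ROI by frame differencing against
an adaptive (exponentially updated) background. The trace is then smoothed,
reduced to a radial coordinate, detrended and min-max normalized.

Pixel coordinates are 0-based with the origin at the top-left of the full
frame; ROIs are half-open ``[x0, x0+width) x [y0, y0+height)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _linear_detrend
from scipy.signal import savgol_filter

from .timeseries import RadialSignal, TimeSeries

__all__ = [
    "VideoROI",
    "MovementTrace",
    "track_barycentre",
    "quantity_of_motion",
    "preprocess",
]


@dataclass(frozen=True)
class VideoROI:
    """Half-open pixel rectangle ``[x0, x0+width) x [y0, y0+height)``."""

    x0: int
    y0: int
    width: int
    height: int
    performer_id: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def check_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape[:2]
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {w}x{h} (width x height)"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


@dataclass
class MovementTrace:
    """Per-frame barycentre coordinates of one ROI, in full-frame pixels."""

    x: np.ndarray
    y: np.ndarray
    rate_hz: float
    roi: VideoROI | None = None
    flags: np.ndarray | None = None  # True where the centroid was carried forward
    backend: str = "greyscale"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.flags is None:
            self.flags = np.zeros(self.x.size, dtype=bool)

    def __len__(self) -> int:
        return self.x.size


def _to_grey(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:
        f = f.mean(axis=2)
    return f


def track_barycentre(
    video_frames,
    roi: VideoROI,
    rate_hz: float = 25.0,
    backend: str = "greyscale",
) -> MovementTrace:
    """Per-frame intensity-weighted centroid of the ROI.

    Parameters
    ----------
    video_frames : iterable of 2-D (grey) or 3-D (RGB) arrays
        At least two frames, all the same shape.
    backend : {"greyscale", "flow"}
        ``greyscale`` weights each pixel by its grey intensity. ``flow``
        weights by dense optical-flow magnitude between consecutive frames
        (iterative Lucas-Kanade, via scikit-image); the first frame falls
        back to greyscale weighting. The backend is recorded on the trace.

    Frames whose ROI is entirely black (zero total weight) re-use the
    previous centroid and are flagged.
    """
    if backend not in ("greyscale", "flow"):
        raise ValueError(f"unknown backend {backend!r}")
    frames = [_to_grey(f) for f in video_frames]
    if len(frames) < 2:
        raise ValueError("track_barycentre requires at least two frames")
    roi.check_within(frames[0].shape)
    ys, xs = roi.slices()
    # pixel-centre coordinate axes in full-frame pixels
    xcoord = np.arange(roi.x0, roi.x0 + roi.width, dtype=float)
    ycoord = np.arange(roi.y0, roi.y0 + roi.height, dtype=float)

    if backend == "flow":
        from skimage.registration import optical_flow_ilk

    x_out = np.empty(len(frames))
    y_out = np.empty(len(frames))
    flags = np.zeros(len(frames), dtype=bool)
    prev_xy = (roi.x0 + (roi.width - 1) / 2.0, roi.y0 + (roi.height - 1) / 2.0)
    for i, frame in enumerate(frames):
        sub = frame[ys, xs]
        if backend == "flow" and i > 0:
            v, u = optical_flow_ilk(frames[i - 1][ys, xs], sub)
            weights = np.hypot(u, v)
        else:
            weights = sub
        total = weights.sum()
        if total <= 0:
            x_out[i], y_out[i] = prev_xy
            flags[i] = True
        else:
            x_out[i] = (weights.sum(axis=0) * xcoord).sum() / total
            y_out[i] = (weights.sum(axis=1) * ycoord).sum() / total
            prev_xy = (x_out[i], y_out[i])
    return MovementTrace(x_out, y_out, rate_hz, roi=roi, flags=flags, backend=backend)


def quantity_of_motion(
    video_frames,
    roi: VideoROI,
    threshold: float = 15.0,
    rate_hz: float = 25.0,
    background_rate: float = 0.05,
    normalize: bool = True,
) -> TimeSeries:
    """Frame-differencing quantity of motion with adaptive background.

    The background is a running exponential mean of past frames
    (``B_t = (1 - a) B_{t-1} + a F_t`` with ``a = background_rate``); each
    frame's QoM is the fraction (or, with ``normalize=False``, the count) of
    ROI pixels whose absolute difference from the current background exceeds
    ``threshold`` grey levels. The first frame is defined as 0.
    """
    frames = [_to_grey(f) for f in video_frames]
    if len(frames) < 2:
        raise ValueError("quantity_of_motion requires at least two frames")
    roi.check_within(frames[0].shape)
    ys, xs = roi.slices()
    area = roi.width * roi.height
    qom = np.zeros(len(frames))
    bg = frames[0][ys, xs].astype(float)
    for i, frame in enumerate(frames[1:], start=1):
        sub = frame[ys, xs]
        changed = np.abs(sub - bg) > threshold
        qom[i] = changed.sum() / area if normalize else float(changed.sum())
        bg = (1.0 - background_rate) * bg + background_rate * sub
    return TimeSeries(qom, rate_hz)


def preprocess(
    trace: MovementTrace,
    savgol_window: int = 5,
    savgol_order: int = 3,
    origin: str = "frame",
) -> RadialSignal:
    """Trace -> radial movement signal: smooth, polar-reduce, detrend, normalize.

    The x and y coordinate series are smoothed with a Savitzky-Golay filter
    (order 3, window 5 frames by default), converted to a radial coordinate
    rho about a pole, linearly detrended, and min-max normalized to [0, 1].

    ``origin="frame"`` (default) takes the pole at the pixel-frame origin, so
    rho is the distance of the raw barycentre from the image corner. Because
    the barycentre sits far from the pole relative to its oscillation
    amplitude, rho is first-order linear in the movement and preserves its
    oscillation frequency. ``origin="mean"`` uses the trace's time-mean
    position instead; note that a symmetric oscillation about the pole then
    folds onto twice its frequency (and pure circular motion about the pole
    collapses to a constant).

    A constant trace yields an all-zero signal (never NaN).
    """
    if origin not in ("frame", "mean"):
        raise ValueError(f"origin must be 'frame' or 'mean', got {origin!r}")
    n = len(trace)
    if n <= savgol_window:
        raise ValueError(
            f"trace of {n} frames is not longer than the filter window {savgol_window}"
        )
    x = savgol_filter(trace.x, savgol_window, savgol_order)
    y = savgol_filter(trace.y, savgol_window, savgol_order)
    if origin == "mean":
        x = x - x.mean()
        y = y - y.mean()
    rho = np.hypot(x, y)
    rho = _linear_detrend(rho, type="linear")
    span = rho.max() - rho.min()
    if span <= 1e-12:
        rho = np.zeros_like(rho)
    else:
        rho = (rho - rho.min()) / span
    return RadialSignal(TimeSeries(rho, trace.rate_hz))
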