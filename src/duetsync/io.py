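"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: TSV for time series and intervals (with a
``#``-prefixed metadata header carrying the configuration hash), CSV for the
predictor table, JSON for configurations and reports, WAV for audio, and the
ELAN tab-delimited export (tier, onset_s, offset_s, text) for annotations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .annotations import BoutSet, Interval, IntervalTier
from .movement import VideoROI
from .timeseries import TimeSeries

__all__ = [
    "config_hash",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_intervals_tsv",
    "read_elan_tsv",
    "write_boutset",
    "read_boutset_tsv",
    "write_wav",
    "read_wav",
    "read_roi_json",
    "write_json",
    "read_video_frames",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration object for output provenance."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_timeseries_tsv(
    path, columns: dict[str, TimeSeries | np.ndarray], rate_hz: float, meta: dict | None = None
) -> None:
    """Multi-column TSV with a shared ``time_s`` axis."""
    arrays = {
        k: (v.values if isinstance(v, TimeSeries) else np.asarray(v))
        for k, v in columns.items()
    }
    n = min(a.size for a in arrays.values())
    df = pd.DataFrame({"time_s": np.arange(n) / rate_hz})
    for k, a in arrays.items():
        df[k] = a[:n]
    with open(path, "w") as fh:
        fh.write(_meta_header({**(meta or {}), "rate_hz": rate_hz}))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_timeseries_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_intervals_tsv(path, tier: IntervalTier, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("tier\tonset_s\toffset_s\ttext\n")
        for iv in tier.intervals:
            fh.write(
                f"{tier.annotator_id}\t{iv.onset_s:.3f}\t{iv.offset_s:.3f}\t"
                f"{iv.label or iv.free_text}\n"
            )


def read_elan_tsv(path) -> list[IntervalTier]:
    """Read an ELAN-style tab-delimited export: tier, onset_s, offset_s, text.

    A header row is skipped if its onset column is not numeric. Rows are
    grouped by tier name; overlapping intervals within a tier are merged with
    a warning on construction.
    """
    tiers: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name = parts[0]
            try:
                onset, offset = float(parts[1]), float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: non-numeric onset/offset") from None
            text = parts[3] if len(parts) > 3 else ""
            tiers.setdefault(name, []).append(Interval(onset, offset, label=text))
    return [IntervalTier(name, ivs) for name, ivs in tiers.items()]


def write_boutset(path, bouts: BoutSet, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header({**(meta or {}), "support": bouts.support}))
        fh.write("onset_s\toffset_s\n")
        for iv in bouts.intervals:
            fh.write(f"{iv.onset_s:.3f}\t{iv.offset_s:.3f}\n")


def read_boutset_tsv(path, support: int = 2) -> BoutSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("onset_s"):
                continue
            if line.strip():
                on, off = map(float, line.split("\t")[:2])
                ivs.append(Interval(on, off))
    return BoutSet(ivs, support=support)


def write_wav(path, samples: np.ndarray, rate_hz: float) -> None:
    x = np.asarray(samples, dtype=float)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.95
    wavfile.write(path, int(rate_hz), (x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    x = np.asarray(data, dtype=float)
    if data.dtype == np.int16:
        x = x / 32768.0
    elif data.dtype == np.int32:
        x = x / 2147483648.0
    return x, float(rate)


def read_roi_json(path) -> dict[str, VideoROI]:
    """ROI config JSON: {performer_id: {x0, y0, width, height}, ...}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        pid: VideoROI(performer_id=pid, **spec) for pid, spec in raw.items()
    }


def write_json(path, obj, meta: dict | None = None) -> None:
    payload = _jsonable(obj)
    if meta:
        payload = {"meta": _jsonable(meta), **(payload if isinstance(payload, dict) else {"data": payload})}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_video_frames(path):
    """Iterate frames of a video container via imageio (native frame rate)."""
    import imageio.v3 as iio

    for frame in iio.imiter(path):
        yield frame
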