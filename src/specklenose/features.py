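"""Chunked time-series feature extraction from displacement traces.

Traces are cut into fixed-length windows (default 40 frames, i.e.
0.2 s at 200 FPS) that never straddle video boundaries; each chunk
yields a fixed 52-feature vector: 13 statistics per channel for the
four channels pos_x, pos_y, dpos_x, dpos_y.

Per channel: mean, std, rms, min, max, range, energy, dominant
frequency, spectral centroid and the band powers over 0-10, 10-30,
30-60 and 60-100 Hz.  Spectral quantities are computed on the
mean-removed, Hann-windowed chunk, so at the default 40-sample window
the frequency resolution is 5 Hz — a deliberate, documented limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracking import DisplacementTrace

__all__ = [
    "CHANNELS",
    "BANDS_HZ",
    "FEATURE_NAMES",
    "GROUP_COLUMNS",
    "Chunk",
    "chunk_trace",
    "spectral_centroid",
    "extract_features",
    "build_feature_table",
    "feature_columns",
    "schema_hash",
]

CHANNELS = ("pos_x", "pos_y", "dpos_x", "dpos_y")
BANDS_HZ = ((0.0, 10.0), (10.0, 30.0), (30.0, 60.0), (60.0, 100.0))
_BASE_STATS = ("mean", "std", "rms", "min", "max", "range", "energy",
               "dominant_freq", "spectral_centroid")
FEATURE_NAMES = tuple(
    f"{ch}__{stat}"
    for ch in CHANNELS
    for stat in _BASE_STATS + tuple(f"bp_{int(lo)}_{int(hi)}" for lo, hi in BANDS_HZ)
)
GROUP_COLUMNS = ("dog_id", "region", "distance_m", "video_tag", "chunk_idx")
LABEL_COLUMN = "smell"


@dataclass
class Chunk:
    """One fixed-length window of a displacement trace with its labels."""

    samples: dict[str, np.ndarray]
    fps: float
    label: str
    group_keys: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.samples["pos_x"])
        if len(self.samples["pos_y"]) != n:
            raise ValueError("pos channels must have equal length")


def chunk_trace(
    trace: DisplacementTrace,
    chunk_len: int = 40,
    stride: int | None = None,
    label: str = "",
    group_keys: Mapping[str, object] | None = None,
) -> list[Chunk]:
    """Cut a trace into windows of ``chunk_len`` frames.

    Windows are non-overlapping by default (``stride = chunk_len``); a
    smaller stride yields overlapping windows for augmentation.  A
    trailing partial window is dropped; a trace shorter than one window
    yields an empty list.  Differential channels are the first
    differences *within* each window, so chunks are self-contained.
    """
    if chunk_len < 2:
        raise ValueError("chunk_len must be >= 2")
    stride = chunk_len if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(trace)
    chunks: list[Chunk] = []
    base_keys = dict(group_keys or {})
    for idx, start in enumerate(range(0, n - chunk_len + 1, stride)):
        px = trace.pos_x[start : start + chunk_len]
        py = trace.pos_y[start : start + chunk_len]
        keys = dict(base_keys)
        keys["chunk_idx"] = idx
        chunks.append(
            Chunk(
                samples={
                    "pos_x": px, "pos_y": py,
                    "dpos_x": np.diff(px), "dpos_y": np.diff(py),
                },
                fps=trace.fps,
                label=label,
                group_keys=keys,
            )
        )
    return chunks


def _windowed_spectrum(series: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    x = series - series.mean()
    x = x * np.hanning(len(x))
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fps)
    return freqs, mag


def spectral_centroid(series: Sequence[float] | np.ndarray, fps: float) -> float:
    """Amplitude-weighted mean frequency over the non-DC one-sided bins.

    Returns 0.0 when every magnitude vanishes (e.g. a constant series).
    """
    series = np.asarray(series, dtype=np.float64)
    if len(series) < 4:
        raise ValueError("spectral centroid requires at least 4 samples")
    freqs, mag = _windowed_spectrum(series, fps)
    mag = mag[1:]
    freqs = freqs[1:]
    total = mag.sum()
    if total <= 0.0:
        return 0.0
    return float((freqs * mag).sum() / total)


def _channel_features(series: np.ndarray, fps: float) -> dict[str, float]:
    if not np.all(np.isfinite(series)):
        raise ValueError("feature input contains non-finite values")
    out = dict(
        mean=float(series.mean()),
        std=float(series.std()),
        rms=float(np.sqrt(np.mean(series**2))),
        min=float(series.min()),
        max=float(series.max()),
    )
    out["range"] = out["max"] - out["min"]
    out["energy"] = float((series**2).sum())
    freqs, mag = _windowed_spectrum(series, fps)
    nz = mag[1:]
    if nz.sum() > 0.0:
        out["dominant_freq"] = float(freqs[1:][int(np.argmax(nz))])
        out["spectral_centroid"] = float((freqs[1:] * nz).sum() / nz.sum())
    else:
        out["dominant_freq"] = 0.0
        out["spectral_centroid"] = 0.0
    power = mag**2
    for lo, hi in BANDS_HZ:
        mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
        out[f"bp_{int(lo)}_{int(hi)}"] = float(power[mask].sum())
    return out


def extract_features(chunk: Chunk) -> dict[str, float]:
    """The 52-feature vector of one chunk, in fixed schema order."""
    values: dict[str, float] = {}
    for ch in CHANNELS:
        stats = _channel_features(np.asarray(chunk.samples[ch], dtype=np.float64), chunk.fps)
        for stat, val in stats.items():
            values[f"{ch}__{stat}"] = val
    return {name: values[name] for name in FEATURE_NAMES}


def feature_columns() -> list[str]:
    return list(FEATURE_NAMES)


def schema_hash() -> str:
    """Stable fingerprint of the feature schema (column names in order)."""
    payload = ",".join(GROUP_COLUMNS + (LABEL_COLUMN,) + FEATURE_NAMES)
    return sha256(payload.encode()).hexdigest()[:16]


def build_feature_table(
    manifest: pd.DataFrame,
    traces: Mapping[str, DisplacementTrace],
    chunk_len: int = 40,
    stride: int | None = None,
) -> pd.DataFrame:
    """Assemble the labelled per-chunk feature table for a dataset.

    One row per chunk; columns are the group keys, the ``smell`` label
    and the 52 features.  Every manifest row must have a trace keyed by
    its ``video_tag``.  The schema hash is recorded in ``attrs``.
    """
    columns = list(GROUP_COLUMNS) + [LABEL_COLUMN] + list(FEATURE_NAMES)
    rows: list[dict] = []
    for _, mrow in manifest.sort_values("video_tag").iterrows():
        tag = mrow["video_tag"]
        if tag not in traces:
            raise KeyError(f"manifest row {tag!r} has no displacement trace")
        trace = traces[tag]
        group = dict(
            dog_id=mrow["dog_id"], region=mrow["region"],
            distance_m=float(mrow["distance_m"]), video_tag=tag,
        )
        for chunk in chunk_trace(
            trace, chunk_len=chunk_len, stride=stride,
            label=str(mrow["smell"]), group_keys=group,
        ):
            row = dict(chunk.group_keys)
            row[LABEL_COLUMN] = chunk.label
            row.update(extract_features(chunk))
            rows.append(row)
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["schema_hash"] = schema_hash()
    return table
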