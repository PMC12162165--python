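"""Speckle displacement tracking by normalized cross-correlation.

A defocused speckle pattern translates rigidly with surface tilt, so
frame-to-frame registration of the pattern yields a tilt-proportional
displacement trace; its Fourier transform is the surface vibration
spectrum.  Registration uses zero-mean normalized cross-correlation
computed in the transform domain (cyclic), with 3-point parabolic
refinement of the correlation peak per axis for subpixel accuracy.

Coordinate convention: x is the column index increasing rightward, y
the row index increasing downward; ``estimate_shift(ref, frame)``
returns the translation that maps ``ref`` onto ``frame``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SpeckleVideo

__all__ = [
    "DegenerateInputError",
    "DisplacementTrace",
    "Spectrum",
    "estimate_shift",
    "track",
    "vibration_spectrum",
]


class DegenerateInputError(ValueError):
    """Raised for inputs the correlation cannot act on (e.g. flat frames)."""


@dataclass
class DisplacementTrace:
    """Per-frame speckle shift (px) and its first differences (px/frame)."""

    pos_x: np.ndarray
    pos_y: np.ndarray
    dpos_x: np.ndarray
    dpos_y: np.ndarray
    fps: float
    video_tag: str = ""

    def __post_init__(self) -> None:
        n = len(self.pos_x)
        if not (len(self.pos_y) == n and len(self.dpos_x) == n - 1 == len(self.dpos_y)):
            raise ValueError("dpos length must equal pos length - 1")
        for arr in (self.pos_x, self.pos_y, self.dpos_x, self.dpos_y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("displacement trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.pos_x)

    def channel(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown channel {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table; dpos is NaN-padded on the first frame."""
        n = len(self)
        pad = lambda d: np.concatenate([[np.nan], d])  # noqa: E731
        return pd.DataFrame(
            dict(
                frame_idx=np.arange(n), pos_x=self.pos_x, pos_y=self.pos_y,
                dpos_x=pad(self.dpos_x), dpos_y=pad(self.dpos_y),
            )
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float, video_tag: str = "") -> "DisplacementTrace":
        df = pd.read_csv(path)
        return cls(
            pos_x=df["pos_x"].to_numpy(), pos_y=df["pos_y"].to_numpy(),
            dpos_x=df["dpos_x"].to_numpy()[1:], dpos_y=df["dpos_y"].to_numpy()[1:],
            fps=fps, video_tag=video_tag,
        )


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on a 0..fps/2 frequency grid."""

    freqs: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.magnitude):
            raise ValueError("freqs and magnitude must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")

    def peak_frequency(self, skip_dc: bool = True) -> float:
        mag = self.magnitude.copy()
        if skip_dc:
            mag[0] = 0.0
        return float(self.freqs[int(np.argmax(mag))])


def _parabolic_offset(c_minus: float, c_zero: float, c_plus: float) -> float:
    """Vertex offset of a 3-point parabola fit around the correlation peak.

    When all three samples are positive the fit is done on their
    logarithms (a Gaussian peak model), which strongly reduces the
    subpixel bias for speckle-like correlation peaks; otherwise the
    plain parabola is used.
    """
    if c_minus > 0.0 and c_zero > 0.0 and c_plus > 0.0:
        c_minus, c_zero, c_plus = np.log([c_minus, c_zero, c_plus])
    denom = c_minus - 2.0 * c_zero + c_plus
    if denom == 0.0:
        return 0.0
    offset = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(offset, -1.0, 1.0))


def _fft2(frame: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero-mean frame spectrum and its energy (for ZNCC normalization)."""
    a = frame.astype(np.float64)
    a -= a.mean()
    energy = float((a * a).sum())
    return np.fft.rfft2(a), energy


def _shift_from_ffts(
    fa: np.ndarray, ea: float, fb: np.ndarray, eb: float, shape: tuple[int, int]
) -> tuple[float, float]:
    if ea <= 0.0 or eb <= 0.0:
        raise DegenerateInputError("constant frame: zero variance, no correlation peak")
    cc = np.fft.irfft2(fb * np.conj(fa), s=shape)
    cc /= np.sqrt(ea * eb)
    ny, nx = cc.shape
    iy, ix = np.unravel_index(int(np.argmax(cc)), cc.shape)
    dy = iy + _parabolic_offset(cc[(iy - 1) % ny, ix], cc[iy, ix], cc[(iy + 1) % ny, ix])
    dx = ix + _parabolic_offset(cc[iy, (ix - 1) % nx], cc[iy, ix], cc[iy, (ix + 1) % nx])
    if dy > ny / 2:
        dy -= ny
    if dx > nx / 2:
        dx -= nx
    return float(dx), float(dy)


def estimate_shift(ref_frame: np.ndarray, frame: np.ndarray) -> tuple[float, float]:
    """Subpixel shift ``(dx, dy)`` mapping ``ref_frame`` onto ``frame``.

    Zero-mean normalized cross-correlation (cyclic, transform domain)
    with 3-point parabolic interpolation of the peak per axis.
    """
    if ref_frame.shape != frame.shape:
        raise ValueError("frames must share a shape")
    fa, ea = _fft2(ref_frame)
    fb, eb = _fft2(frame)
    return _shift_from_ffts(fa, ea, fb, eb, ref_frame.shape)


def track(video: SpeckleVideo, mode: str = "sequential") -> DisplacementTrace:
    """Displacement trace of a video.

    ``sequential`` (default) estimates the shift between consecutive
    frames and accumulates it — robust to slow pattern decorrelation.
    ``anchored`` registers every frame against frame 0.  ``pos`` is
    relative to frame 0 in both modes; no drift correction is applied.
    """
    frames = video.frames
    if frames.shape[0] < 2:
        raise ValueError("tracking requires at least 2 frames")
    if mode not in ("sequential", "anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    n = frames.shape[0]
    shape = frames.shape[1:]
    pos_x = np.zeros(n)
    pos_y = np.zeros(n)
    if mode == "anchored":
        f0, e0 = _fft2(frames[0])
        for i in range(1, n):
            fi, ei = _fft2(frames[i])
            pos_x[i], pos_y[i] = _shift_from_ffts(f0, e0, fi, ei, shape)
    else:
        prev_fft, prev_energy = _fft2(frames[0])
        for i in range(1, n):
            cur_fft, cur_energy = _fft2(frames[i])
            dx, dy = _shift_from_ffts(prev_fft, prev_energy, cur_fft, cur_energy, shape)
            pos_x[i] = pos_x[i - 1] + dx
            pos_y[i] = pos_y[i - 1] + dy
            prev_fft, prev_energy = cur_fft, cur_energy
    return DisplacementTrace(
        pos_x=pos_x, pos_y=pos_y,
        dpos_x=np.diff(pos_x), dpos_y=np.diff(pos_y),
        fps=video.fps, video_tag=video.video_tag,
    )


def vibration_spectrum(
    trace: DisplacementTrace,
    channel: str = "pos_x",
    detrend: bool = True,
    window: str = "hann",
) -> Spectrum:
    """One-sided magnitude spectrum of a trace channel.

    ``detrend`` removes the mean; ``window`` is ``"hann"`` or
    ``"rectangular"`` (the latter keeps pure tones exactly on one bin).
    """
    series = np.asarray(trace.channel(channel), dtype=np.float64)
    if len(series) < 8:
        raise ValueError("spectrum requires at least 8 samples")
    if detrend:
        series = series - series.mean()
    if window == "hann":
        series = series * np.hanning(len(series))
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")
    mag = np.abs(np.fft.rfft(series))
    freqs = np.fft.rfftfreq(len(series), d=1.0 / trace.fps)
    return Spectrum(freqs=freqs, magnitude=mag)
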