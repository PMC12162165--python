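"""Physics-based synthetic secondary-speckle video generator.

The generator stands in for in-vivo recordings of laser speckle on the
skin over three brain regions (olfactory bulb, hippocampus, amygdala)
while a smell stimulus is presented.  It emulates the physical chain the
sensing principle rests on:

1. a random phase screen models the surface roughness;
2. the detected speckle intensity is the squared magnitude of the
   far-field (Fourier) transform of a circular pupil carrying that
   random phase — fully developed speckle with unit contrast and
   negative-exponential intensity statistics;
3. surface tilt translates the pattern rigidly; translation is applied
   in the transform domain (exact to machine precision, including
   subpixel shifts);
4. a tilt time series encodes the class signal: each (smell, region)
   pair has sinusoidal components plus a cardiac-like pulse train and a
   stochastic tilt noise floor, attenuated with sensing distance;
5. a sensor model quantizes to a configurable bit depth and adds read
   noise and optional shot noise.

What is deliberately NOT modelled: speckle decorrelation ("boiling"),
reflection-geometry doubling, fur/tissue scattering, and hemodynamic
waveforms beyond the pulse train.  Translation-only motion is the
operating regime of tilt-based speckle vibrometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SMELLS",
    "REGIONS",
    "DISTANCES_M",
    "ConfigurationError",
    "PhaseScreen",
    "TiltTrace",
    "ClassSignalParams",
    "SensorConfig",
    "RecordingProtocol",
    "SpeckleVideo",
    "DatasetDesign",
    "make_phase_screen",
    "speckle_intensity",
    "shift_intensity",
    "render_frame",
    "default_signal_params",
    "tilt_signal",
    "simulate_recording",
    "generate_dataset",
    "video_seed",
]

SMELLS = ("control", "alcohol", "marijuana", "menthol", "garlic")
REGIONS = ("olfactory_bulb", "hippocampus", "amygdala")
DISTANCES_M = (0.1, 1.0)

#: Distinct sinusoidal signature per smell (Hz).  Pairs are chosen so the
#: classes occupy separated parts of the 0–100 Hz band observable at
#: 200 FPS, which makes the default scenario separable by band-power
#: features — a synthetic convenience, not a biological claim.
SMELL_COMPONENT_FREQS: dict[str, tuple[float, float]] = {
    "control": (5.0, 55.0),
    "alcohol": (12.0, 34.0),
    "marijuana": (18.0, 44.0),
    "menthol": (26.0, 52.0),
    "garlic": (8.0, 59.0),
}

#: Relative tilt amplitude per region; the amygdala-like cell carries the
#: strongest signal so the qualitative region ranking reported for real
#: recordings is reproducible as a synthetic scenario.
REGION_AMPLITUDE_SCALE: dict[str, float] = {
    "amygdala": 1.0,
    "olfactory_bulb": 0.6,
    "hippocampus": 0.35,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# --------------------------------------------------------------------------
# phase screen and speckle rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseScreen:
    """Square grid of i.i.d. surface-roughness phases on [0, 2*pi)."""

    phases: np.ndarray
    grid_size: int
    seed: int

    def __post_init__(self) -> None:
        if self.phases.shape != (self.grid_size, self.grid_size):
            raise ConfigurationError("phase grid must be square of side grid_size")


def make_phase_screen(grid_size: int, seed: int, frame_size: int | None = None) -> PhaseScreen:
    """Draw a uniform random phase screen.

    ``grid_size`` must be at least twice ``frame_size`` (when given) so a
    guard band remains around the cropped frame for pattern shifting.
    """
    if frame_size is not None and grid_size < 2 * frame_size:
        raise ConfigurationError(
            f"grid_size {grid_size} must be >= 2x frame size {frame_size} (guard band)"
        )
    if grid_size < 2:
        raise ConfigurationError("grid_size must be >= 2")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(grid_size, grid_size))
    return PhaseScreen(phases=phases, grid_size=grid_size, seed=int(seed))


def speckle_intensity(screen: PhaseScreen, pupil_frac: float = 0.48) -> np.ndarray:
    """Far-field speckle intensity of a circular pupil carrying the screen.

    The pupil (diameter = ``pupil_frac`` of the frequency grid) limits
    the field bandwidth, giving a mean speckle grain of roughly
    ``1 / pupil_frac`` pixels.  ``pupil_frac < 0.5`` keeps the intensity
    spectrum (the pupil autocorrelation) strictly below Nyquist, so
    transform-domain translation is exact and composes exactly.
    """
    if not 0 < pupil_frac < 0.5:
        raise ConfigurationError("pupil_frac must lie in (0, 0.5)")
    n = screen.grid_size
    u = np.fft.fftfreq(n)
    rr = u[:, None] ** 2 + u[None, :] ** 2
    pupil = rr <= (pupil_frac / 2.0) ** 2
    aperture = np.where(pupil, np.exp(1j * screen.phases), 0.0)
    field_ = np.fft.ifft2(aperture) * n
    return np.abs(field_) ** 2


def _shift_from_spectrum(
    spectrum: np.ndarray, shape: tuple[int, int], shift: tuple[float, float]
) -> np.ndarray:
    dx, dy = shift
    ny, nx = shape
    ramp_y = np.exp(-2j * np.pi * np.fft.fftfreq(ny) * dy)[:, None]
    ramp_x = np.exp(-2j * np.pi * np.fft.rfftfreq(nx) * dx)[None, :]
    out = np.fft.irfft2(spectrum * ramp_y * ramp_x, s=shape)
    # band-limited interpolation can leave a negligible negative ripple
    np.maximum(out, 0.0, out=out)
    return out


def shift_intensity(intensity: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Translate a periodic band-limited intensity by ``(dx, dy)`` pixels.

    Uses the Fourier shift property; exact for integer shifts and for
    subpixel shifts of a band-limited pattern (x = column, y = row).
    """
    return _shift_from_spectrum(np.fft.rfft2(intensity), intensity.shape, shift)


@dataclass(frozen=True)
class SensorConfig:
    """Camera sensor model.

    ``bit_depth`` of ``None`` selects a noiseless floating-point output
    normalized to unit mean — the path used for validating the speckle
    statistics.  ``mean_fill`` places the mean intensity at that fraction
    of full scale to leave headroom for the exponential tail.
    """

    bit_depth: int | None = 8
    read_noise_dn: float = 2.0
    shot_noise: bool = False
    mean_fill: float = 0.2

    def __post_init__(self) -> None:
        if self.bit_depth is not None and self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8, 16 or None")
        if self.read_noise_dn < 0:
            raise ConfigurationError("read_noise_dn must be >= 0")
        if not 0 < self.mean_fill < 1:
            raise ConfigurationError("mean_fill must lie in (0, 1)")


def _crop_center(arr: np.ndarray, size: int) -> np.ndarray:
    n = arr.shape[0]
    lo = (n - size) // 2
    return arr[lo : lo + size, lo : lo + size]


def render_frame(
    screen: PhaseScreen,
    shift: tuple[float, float] = (0.0, 0.0),
    frame_size: int = 224,
    pupil_frac: float = 0.48,
    sensor: SensorConfig | None = None,
    rng: np.random.Generator | None = None,
    shift_bound: float = 64.0,
    _base_intensity: np.ndarray | None = None,
    _base_spectrum: np.ndarray | None = None,
) -> np.ndarray:
    """Render one detector frame at the given pattern shift.

    The full-field intensity is rendered once from the phase screen,
    translated in the transform domain by ``shift`` (exact subpixel),
    centre-cropped to ``frame_size`` and passed through the sensor model.
    ``_base_intensity`` lets callers reuse the rendered field across
    frames of one recording.
    """
    dx, dy = shift
    if abs(dx) > shift_bound or abs(dy) > shift_bound:
        raise ValueError(f"shift {shift} exceeds guard band +/-{shift_bound} px")
    sensor = sensor or SensorConfig()
    base = _base_intensity if _base_intensity is not None else speckle_intensity(screen, pupil_frac)
    if not (dx or dy):
        moved = base
    elif _base_spectrum is not None:
        moved = _shift_from_spectrum(_base_spectrum, base.shape, shift)
    else:
        moved = shift_intensity(base, shift)
    frame = _crop_center(moved, frame_size)
    mean = base.mean()
    if sensor.bit_depth is None:
        return frame / mean
    full_scale = 2**sensor.bit_depth - 1
    dn = frame * (sensor.mean_fill * full_scale / mean)
    if sensor.shot_noise:
        if rng is None:
            raise ConfigurationError("shot noise requires an rng")
        dn = rng.poisson(dn).astype(np.float64)
    if sensor.read_noise_dn > 0:
        if rng is None:
            raise ConfigurationError("read noise requires an rng")
        dn = dn + rng.normal(0.0, sensor.read_noise_dn, size=dn.shape)
    dn = np.clip(np.rint(dn), 0, full_scale)
    return dn.astype(np.uint8 if sensor.bit_depth == 8 else np.uint16)


# --------------------------------------------------------------------------
# class-specific tilt signals
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSignalParams:
    """Tilt-signal signature of one (smell, region) condition.

    Amplitudes are surface tilts in microradians; ``distance_gain`` maps
    sensing distance (m) to an attenuation factor so the 1 m condition
    is weaker than the 0.1 m one.
    """

    smell: str
    region: str
    component_freqs: tuple[float, ...]
    component_amps: tuple[float, ...]
    pulse_rate: float = 2.0
    pulse_amp: float = 0.3
    noise_floor: float = 0.2
    distance_gain: dict[float, float] = field(
        default_factory=lambda: {0.1: 1.0, 1.0: 0.4}
    )

    def __post_init__(self) -> None:
        if len(self.component_freqs) != len(self.component_amps):
            raise ConfigurationError("component freq/amp lists must have equal length")
        if any(f <= 0 for f in self.component_freqs):
            raise ConfigurationError("component frequencies must be positive")
        if any(a < 0 for a in self.component_amps):
            raise ConfigurationError("component amplitudes must be >= 0")


def default_signal_params(smell: str, region: str) -> ClassSignalParams:
    """Default signature: smell picks the frequency pair, region the amplitude."""
    if smell not in SMELL_COMPONENT_FREQS:
        raise ConfigurationError(f"unknown smell {smell!r}")
    if region not in REGION_AMPLITUDE_SCALE:
        raise ConfigurationError(f"unknown region {region!r}")
    scale = REGION_AMPLITUDE_SCALE[region]
    return ClassSignalParams(
        smell=smell,
        region=region,
        component_freqs=SMELL_COMPONENT_FREQS[smell],
        component_amps=(1.0 * scale, 0.7 * scale),
    )


@dataclass(frozen=True)
class TiltTrace:
    """Per-frame surface tilt (microradians) about the two axes."""

    theta_x: np.ndarray
    theta_y: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if len(self.theta_x) != len(self.theta_y):
            raise ConfigurationError("theta_x and theta_y must have equal length")
        if not self.fps > 0:
            raise ConfigurationError("fps must be positive")

    def __len__(self) -> int:
        return len(self.theta_x)


def tilt_signal(
    params: ClassSignalParams,
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    distance_m: float = 0.1,
    amplitude_scale: float = 1.0,
) -> TiltTrace:
    """Generate the tilt time series for one recording.

    theta(t) = sum_j amp_j sin(2 pi f_j t + phi_j) + cardiac pulse train
    + Gaussian tilt noise, all scaled by the distance gain.  Component
    phases are drawn independently per axis.  ``amplitude_scale``
    rescales the deterministic signal only (used for SNR sweeps).
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    nyquist = fps / 2.0
    for f in (*params.component_freqs, params.pulse_rate):
        if f >= nyquist:
            raise ConfigurationError(f"component at {f} Hz aliases at fps {fps}")
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    gain = params.distance_gain.get(distance_m)
    if gain is None:
        raise ConfigurationError(f"no distance_gain entry for {distance_m} m")

    def one_axis() -> np.ndarray:
        theta = np.zeros(n)
        for f, a in zip(params.component_freqs, params.component_amps):
            theta += a * np.sin(2.0 * np.pi * f * t + rng.uniform(0.0, 2.0 * np.pi))
        # cardiac-like train: sharpened half-wave rectified sinusoid
        pulse_phase = rng.uniform(0.0, 2.0 * np.pi)
        pulse = np.maximum(np.sin(2.0 * np.pi * params.pulse_rate * t + pulse_phase), 0.0)
        theta += params.pulse_amp * pulse**6
        theta *= amplitude_scale
        if params.noise_floor > 0:
            theta += rng.normal(0.0, params.noise_floor, size=n)
        return gain * theta

    return TiltTrace(theta_x=one_axis(), theta_y=one_axis(), fps=fps)


# --------------------------------------------------------------------------
# recordings and datasets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RecordingProtocol:
    """Acquisition protocol for one video.

    Defaults mirror the experimental protocol the pipeline targets:
    5 s recordings repeated 4 times at 200 FPS, 224 x 224 frames.
    ``gain_px_per_urad`` is the tilt-to-shift coupling g: the transverse
    speckle translation (pixels) produced per microradian of surface
    tilt.
    """

    duration_s: float = 5.0
    repeats: int = 4
    fps: float = 200.0
    frame_size: int = 224
    field_size: int = 512
    pupil_frac: float = 0.48
    gain_px_per_urad: float = 0.5
    shift_bound: float = 64.0
    sensor: SensorConfig = field(default_factory=SensorConfig)

    def __post_init__(self) -> None:
        if self.gain_px_per_urad <= 0:
            raise ConfigurationError("gain_px_per_urad must be positive")
        if self.field_size < 2 * self.frame_size:
            raise ConfigurationError("field_size must be >= 2x frame_size (guard band)")
        if self.repeats < 1 or self.duration_s <= 0 or self.fps <= 0:
            raise ConfigurationError("repeats >= 1, duration_s > 0 and fps > 0 required")

    @property
    def frames_per_video(self) -> int:
        return int(round(self.duration_s * self.fps)) * self.repeats


@dataclass
class SpeckleVideo:
    """A speckle recording: frame stack plus acquisition/label metadata."""

    frames: np.ndarray  # (T, H, W)
    fps: float
    dog_id: str
    region: str
    smell: str
    distance_m: float
    video_tag: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_recording(
    params: ClassSignalParams,
    protocol: RecordingProtocol,
    rng: np.random.Generator | int,
    dog_id: str = "sim",
    distance_m: float = 0.1,
    video_tag: str | None = None,
    amplitude_scale: float = 1.0,
) -> SpeckleVideo:
    """Simulate one labelled video of ``repeats`` back-to-back recordings.

    Each repeat draws a fresh phase screen and tilt trace; the per-frame
    pattern shift is ``g * (theta_x, theta_y)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = protocol.gain_px_per_urad
    chunks: list[np.ndarray] = []
    for _ in range(protocol.repeats):
        screen_seed = int(rng.integers(0, 2**31))
        screen = make_phase_screen(protocol.field_size, screen_seed, protocol.frame_size)
        base = speckle_intensity(screen, protocol.pupil_frac)
        base_spectrum = np.fft.rfft2(base)
        tilt = tilt_signal(
            params, protocol.duration_s, protocol.fps, rng,
            distance_m=distance_m, amplitude_scale=amplitude_scale,
        )
        frames = np.empty(
            (len(tilt), protocol.frame_size, protocol.frame_size),
            dtype=np.uint8 if protocol.sensor.bit_depth == 8 else
            (np.uint16 if protocol.sensor.bit_depth == 16 else np.float64),
        )
        for i in range(len(tilt)):
            frames[i] = render_frame(
                screen,
                shift=(g * tilt.theta_x[i], g * tilt.theta_y[i]),
                frame_size=protocol.frame_size,
                pupil_frac=protocol.pupil_frac,
                sensor=protocol.sensor,
                rng=rng,
                shift_bound=protocol.shift_bound,
                _base_intensity=base,
                _base_spectrum=base_spectrum,
            )
        chunks.append(frames)
    tag = video_tag or f"{dog_id}-{params.region}-{params.smell}-{distance_m}m"
    return SpeckleVideo(
        frames=np.concatenate(chunks, axis=0),
        fps=protocol.fps,
        dog_id=dog_id,
        region=params.region,
        smell=params.smell,
        distance_m=distance_m,
        video_tag=tag,
    )


@dataclass(frozen=True)
class DatasetDesign:
    """Factorial design of a synthetic study.

    Default mirrors the target study layout: 4 dogs x 3 regions x
    5 smells x 2 distances, 3 videos per cell.
    """

    dogs: tuple[str, ...] = ("lili", "thomas", "tanin", "johny")
    regions: tuple[str, ...] = REGIONS
    smells: tuple[str, ...] = SMELLS
    distances_m: tuple[float, ...] = DISTANCES_M
    videos_per_cell: int = 3
    protocol: RecordingProtocol = field(default_factory=RecordingProtocol)
    amplitude_scale: float = 1.0

    def cells(self) -> Iterator[tuple[str, str, str, float, int]]:
        for dog in self.dogs:
            for region in self.regions:
                for smell in self.smells:
                    for dist in self.distances_m:
                        for v in range(self.videos_per_cell):
                            yield dog, region, smell, dist, v

    @property
    def n_videos(self) -> int:
        return (
            len(self.dogs) * len(self.regions) * len(self.smells)
            * len(self.distances_m) * self.videos_per_cell
        )


def video_seed(master_seed: int, index: int) -> int:
    """Counter-based per-video seed: hash of (master_seed, video index)."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def generate_dataset(
    design: DatasetDesign,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SpeckleVideo], pd.DataFrame]:
    """Generate every video of the design plus its manifest.

    Seeds derive deterministically from ``(master_seed, video index)``,
    so regeneration is byte-identical and any single video can be
    re-simulated from its manifest row alone.  With ``out_dir`` set each
    video is written as a multi-page grayscale TIFF.
    """
    from . import io as _io  # local import to avoid a cycle

    videos: list[SpeckleVideo] = []
    rows: list[dict] = []
    seen_tags: set[str] = set()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for index, (dog, region, smell, dist, v) in enumerate(design.cells()):
        seed = video_seed(master_seed, index)
        tag = f"{dog}-{region}-{smell}-{dist}m-v{v:02d}"
        if tag in seen_tags:
            raise ConfigurationError(f"duplicate video_tag {tag!r}")
        seen_tags.add(tag)
        params = default_signal_params(smell, region)
        video = simulate_recording(
            params,
            design.protocol,
            np.random.default_rng(seed),
            dog_id=dog,
            distance_m=dist,
            video_tag=tag,
            amplitude_scale=design.amplitude_scale,
        )
        path = ""
        if out_path is not None:
            path = str(out_path / f"{tag}.tif")
            _io.write_video(video, path)
        else:
            videos.append(video)
        rows.append(
            dict(
                video_tag=tag, path=path, dog_id=dog, region=region, smell=smell,
                distance_m=dist, fps=design.protocol.fps,
                n_frames=design.protocol.frames_per_video, seed=seed,
            )
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "video_tag", "path", "dog_id", "region", "smell",
            "distance_m", "fps", "n_frames", "seed",
        ],
    )
    return videos, manifest
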