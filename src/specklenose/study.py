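"""Desk-scale study scenarios: the standard conditions used throughout.

The full-scale protocol (224 px frames, 5 s x 4 repeats, 4 dogs, 3
regions, 2 distances, 3+ videos per cell) is expensive to simulate; the
desk-scale scenario keeps the full physics and protocol structure but
shrinks the sizes: 128 px frames on a 256 px field, 1 s single-repeat
videos at 200 FPS, two dogs, the high-amplitude (amygdala-like) region,
both sensing distances, five videos per cell.  These are the package's
standard study conditions — analysis scripts, the test suite and the
reproduction script all run the same ones.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .boost import GBTParams
from .pipeline import ExperimentConfig, split_dataset, train_eval_cell, simulate_and_featurize
from .simulate import DatasetDesign, RecordingProtocol

__all__ = [
    "DESK_PROTOCOL",
    "desk_design",
    "main_config",
    "snr_config",
    "run_snr_level",
]

#: Desk-scale acquisition protocol (full physics, reduced sizes).
DESK_PROTOCOL = RecordingProtocol(
    duration_s=1.0, repeats=1, fps=200.0, frame_size=128, field_size=256
)


def desk_design(
    dogs: tuple[str, ...] = ("lili", "thomas"),
    distances_m: tuple[float, ...] = (0.1, 1.0),
    videos_per_cell: int = 5,
    amplitude_scale: float = 1.0,
    duration_s: float = 1.0,
) -> DatasetDesign:
    """Amygdala-cell desk-scale design; 5 smells always included."""
    return DatasetDesign(
        dogs=dogs,
        regions=("amygdala",),
        distances_m=distances_m,
        videos_per_cell=videos_per_cell,
        protocol=replace(DESK_PROTOCOL, duration_s=duration_s),
        amplitude_scale=amplitude_scale,
    )


def main_config(seed: int = 0) -> ExperimentConfig:
    """The main desk-scale experiment: both distances, 5 videos/cell."""
    return ExperimentConfig(
        design=desk_design(),
        params=GBTParams(n_rounds=40, max_depth=3),
        seed=seed,
    )


def snr_config(amplitude_scale: float, seed: int) -> ExperimentConfig:
    """Smaller single-distance config for signal-amplitude sweeps."""
    return ExperimentConfig(
        design=desk_design(
            distances_m=(0.1,), videos_per_cell=3,
            amplitude_scale=amplitude_scale, duration_s=0.8,
        ),
        params=GBTParams(n_rounds=30, max_depth=3),
        seed=seed,
    )


def run_snr_level(amplitude_scale: float, seed: int) -> float:
    """Held-out macro accuracy of one amplitude level at one seed."""
    config = snr_config(amplitude_scale, seed)
    _, _, table = simulate_and_featurize(config)
    split = split_dataset(table, config.fractions, seed=config.seed)
    cell = train_eval_cell(
        table, split, config.params, scope="aggregated",
        region="amygdala", distance_m=0.1,
    )
    return float(np.trace(cell.matrix.counts) / cell.matrix.n)
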