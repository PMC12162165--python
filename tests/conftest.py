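"""Shared fixtures: small simulated recordings and feature tables.

Everything is generated at test time from fixed seeds; the simulation
sizes are deliberately small (128 px frames, 1 s recordings) so the
suite stays fast while exercising the full physics chain.
"""

from __future__ import annotations

import numpy as np
import pytest

import specklenose as sn
from specklenose.pipeline import ExperimentConfig, simulate_and_featurize
from specklenose.simulate import DatasetDesign, RecordingProtocol


SMALL_PROTOCOL = RecordingProtocol(
    duration_s=1.0, repeats=1, frame_size=128, field_size=256
)


@pytest.fixture(scope="session")
def tone_video() -> sn.SpeckleVideo:
    """One recording whose tilt is dominated by a pure 10 Hz component."""
    params = sn.ClassSignalParams(
        smell="alcohol", region="amygdala",
        component_freqs=(10.0,), component_amps=(1.0,),
        pulse_amp=0.0, noise_floor=0.02,
    )
    return sn.simulate_recording(params, SMALL_PROTOCOL, rng=123, dog_id="dog0")


@pytest.fixture(scope="session")
def small_dataset():
    """2 dogs x 5 smells x 3 videos in one amygdala cell, featurized."""
    design = DatasetDesign(
        dogs=("d1", "d2"), regions=("amygdala",), distances_m=(0.1,),
        videos_per_cell=3, protocol=SMALL_PROTOCOL,
    )
    config = ExperimentConfig(design=design, seed=7)
    manifest, traces, table = simulate_and_featurize(config)
    return manifest, traces, table


@pytest.fixture(scope="session")
def classification_table():
    """Purely synthetic 200-row, 5-class feature table (no simulation).

    Class structure: 6 informative Gaussian features with class-specific
    means plus 4 noise features — separable but not trivially so.
    """
    import pandas as pd

    rng = np.random.default_rng(42)
    n_per, n_classes = 40, 5
    centers = rng.normal(0.0, 2.0, size=(n_classes, 6))
    rows = []
    for c in range(n_classes):
        X = centers[c] + rng.normal(0.0, 1.0, size=(n_per, 6))
        noise = rng.normal(0.0, 1.0, size=(n_per, 4))
        for i in range(n_per):
            rows.append(
                dict(
                    smell=f"class_{c}",
                    **{f"g{j}": X[i, j] for j in range(6)},
                    **{f"n{j}": noise[i, j] for j in range(4)},
                )
            )
    return pd.DataFrame(rows).sample(frac=1.0, random_state=1).reset_index(drop=True)
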