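"""Reading and writing video stacks, manifests, traces and tables.

Videos travel as multi-page grayscale TIFF stacks (one file per
recording); ``.npy`` array stacks are accepted by the same reader as a
lightweight alternative.  The manifest is a CSV with one row per video
carrying labels and provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import SpeckleVideo

MANIFEST_COLUMNS = [
    "video_tag", "path", "dog_id", "region", "smell",
    "distance_m", "fps", "n_frames", "seed",
]


def write_video(video: SpeckleVideo, path: str | Path) -> None:
    """Write a frame stack as a multi-page TIFF (or ``.npy`` stack)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, video.frames)
    else:
        tifffile.imwrite(path, video.frames, photometric="minisblack")


def read_video(path: str | Path, manifest_row: pd.Series | dict) -> SpeckleVideo:
    """Load a video stack and attach metadata from its manifest row."""
    path = Path(path)
    frames = np.load(path) if path.suffix == ".npy" else tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    row = dict(manifest_row)
    return SpeckleVideo(
        frames=frames,
        fps=float(row["fps"]),
        dog_id=str(row["dog_id"]),
        region=str(row["region"]),
        smell=str(row["smell"]),
        distance_m=float(row["distance_m"]),
        video_tag=str(row["video_tag"]),
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def iter_videos(manifest: pd.DataFrame):
    """Yield ``SpeckleVideo`` objects for every manifest row."""
    for _, row in manifest.iterrows():
        yield read_video(row["path"], row)
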