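#!/usr/bin/env python
"""Chunk the traces and extract the 52-feature table.

40-frame windows (0.2 s at 200 FPS) per video, 13 features per channel
over pos_x/pos_y/dpos_x/dpos_y, labelled with the smell class and the
grouping keys used for leakage-safe splitting.
"""

from pathlib import Path

from specklenose import io as sio
from specklenose.features import build_feature_table, schema_hash
from specklenose.tracking import DisplacementTrace

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "dataset"
TRACE_DIR = ROOT / "scratch" / "traces"
OUT = ROOT / "scratch" / "features.csv"


def main() -> None:
    manifest = sio.read_manifest(DATA_DIR / "manifest.csv")
    traces = {
        row.video_tag: DisplacementTrace.from_csv(
            TRACE_DIR / f"{row.video_tag}.csv", fps=row.fps, video_tag=row.video_tag
        )
        for row in manifest.itertuples()
    }
    table = build_feature_table(manifest, traces, chunk_len=40)
    table.to_csv(OUT, index=False)
    print(f"wrote {len(table)} chunks x {table.shape[1]} columns -> {OUT}")
    print(f"schema hash: {schema_hash()}")
    print(table.groupby(["smell", "distance_m"]).size().rename("n_chunks").to_string())


if __name__ == "__main__":
    main()
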