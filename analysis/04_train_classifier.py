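#!/usr/bin/env python
"""Split by video tag and train the boosted-tree classifier per cell.

One model per sensing distance (dogs pooled, amygdala cell); the split
is 80/20 per dog over video tags so chunks of one video never cross
partitions.  Models are saved as JSON; the per-round training objective
is logged to results/.
"""

from pathlib import Path

import pandas as pd

from specklenose.boost import GBTParams, fit
from specklenose.pipeline import split_dataset

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "scratch" / "features.csv"
MODEL_DIR = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"
PARAMS = GBTParams(n_rounds=40, max_depth=3)


def main() -> None:
    table = pd.read_csv(FEATURES)
    split = split_dataset(table, seed=SEED)
    MODEL_DIR.mkdir(parents=True, exist_ok=True)
    logs = []
    for dist, sub in table.groupby("distance_m"):
        train = sub[split.mask(sub, "train")]
        ensemble = fit(train, PARAMS)
        ensemble.save(MODEL_DIR / f"model_{dist}m.json")
        for entry in ensemble.train_log:
            logs.append(dict(distance_m=dist, **entry))
        final = ensemble.train_log[-1]
        print(f"{dist} m: trained on {len(train)} chunks, "
              f"final train log-loss {final['log_loss']:.3f} "
              f"(objective {final['objective']:.3f})")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(logs).to_csv(RESULTS / "training_log.csv", index=False)
    print(f"models -> {MODEL_DIR}")


if __name__ == "__main__":
    main()
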