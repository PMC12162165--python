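#!/usr/bin/env python
"""TPE-style hyperparameter search against a random-search baseline.

Maximizes validation macro-F1 over learning rate and tree depth (the
two hyperparameters singled out for tuning), 15 trials per sampler, on
the near-distance cell.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from specklenose.boost import GBTParams, fit, predict_labels
from specklenose.evaluation import confusion_matrix, macro_metrics
from specklenose.pipeline import split_dataset
from specklenose.tuning import FloatParam, IntParam, tune

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "scratch" / "features.csv"
RESULTS = ROOT / "results"
SPACE = {"eta": FloatParam(0.02, 0.5, log=True), "max_depth": IntParam(2, 6)}
BASE = GBTParams(n_rounds=25, max_depth=3)


def main() -> None:
    table = pd.read_csv(FEATURES)
    table = table[table["distance_m"] == 0.1]
    split = split_dataset(table, seed=SEED)
    train = table[split.mask(table, "train")]
    val = table[split.mask(table, "validation")]
    class_order = sorted(table["smell"].unique())

    def objective(params_dict: dict) -> float:
        ens = fit(train, replace(BASE, **params_dict))
        cm = confusion_matrix(
            val["smell"].tolist(), predict_labels(ens, val).tolist(), class_order
        )
        f1 = macro_metrics(cm).f1
        return float("nan") if f1 is None else f1

    frames = []
    for sampler in ("random", "tpe"):
        log = tune(SPACE, objective, n_trials=15, sampler=sampler, seed=SEED)
        frames.append(log.to_dataframe().assign(sampler=sampler))
        print(f"{sampler}: best macro-F1 {log.best_value:.4f} at {log.best_params}")
    RESULTS.mkdir(exist_ok=True)
    pd.concat(frames).to_csv(RESULTS / "tuning_trials.csv", index=False)
    print(f"trial log -> {RESULTS / 'tuning_trials.csv'}")


if __name__ == "__main__":
    main()
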