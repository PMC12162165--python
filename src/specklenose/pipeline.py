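"""Experiment orchestration: split, train, evaluate, aggregate, report.

The unit of train/validation assignment is the *video tag*: every chunk
of a video follows its video's partition, so no chunk-level information
leaks between partitions.  Splitting is per dog — each dog contributes
the target fraction of its videos to each partition — with a
class-interleaved shuffle so every partition stays representative of
the smell classes.

Analysis cells mirror the study design: one model per (region,
distance) with dogs pooled ("aggregated" scope), and optionally one per
(dog, region, distance) ("per_dog" scope).  The control class is
included in aggregated cells and excluded in per-dog cells by default;
both are toggleable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import features as feat
from . import tracking
from .boost import Ensemble, GBTParams, fit, predict_labels
from .evaluation import ConfusionMatrix, confusion_matrix, macro_metrics, metrics_table, normalize_rows
from .simulate import DatasetDesign, generate_dataset
from .tuning import FloatParam, IntParam, TrialLog, tune

__all__ = [
    "DatasetSplit",
    "ExperimentConfig",
    "CellResult",
    "Report",
    "split_dataset",
    "train_eval_cell",
    "aggregate_by_region",
    "run_experiment",
]

DEFAULT_FRACTIONS = {"train": 0.8, "validation": 0.2}
THREE_WAY_FRACTIONS = {"train": 0.7, "validation": 0.15, "test": 0.15}


@dataclass
class DatasetSplit:
    """Per-dog assignment of video tags to partitions."""

    assignment: dict[str, str]
    fractions: dict[str, float]
    seed: int

    def partition_of(self, video_tag: str) -> str:
        return self.assignment[video_tag]

    def tags(self, partition: str) -> list[str]:
        return sorted(t for t, p in self.assignment.items() if p == partition)

    def mask(self, table: pd.DataFrame, partition: str) -> np.ndarray:
        return table["video_tag"].map(self.assignment).eq(partition).to_numpy()


def _largest_remainder(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    names = list(fractions)
    exact = {k: n * fractions[k] for k in names}
    counts = {k: int(np.floor(exact[k])) for k in names}
    short = n - sum(counts.values())
    remainders = sorted(names, key=lambda k: (-(exact[k] - counts[k]), names.index(k)))
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def split_dataset(
    table: pd.DataFrame,
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> DatasetSplit:
    """Assign every video tag to a partition, per dog.

    ``table`` needs ``dog_id``, ``video_tag`` and ``smell`` columns (a
    manifest or a feature table).  Within each dog, videos are shuffled
    per smell class and interleaved across classes before the cumulative
    cut, so partitions keep the class distribution; per-dog partition
    sizes follow largest-remainder rounding of the fractions.
    """
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    videos = table[["dog_id", "video_tag", "smell"]].drop_duplicates("video_tag")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for dog in sorted(videos["dog_id"].unique()):
        sub = videos[videos["dog_id"] == dog]
        per_smell: list[list[str]] = []
        smells = sorted(sub["smell"].unique())
        rng.shuffle(smells)
        for smell in smells:
            tags = sorted(sub.loc[sub["smell"] == smell, "video_tag"])
            rng.shuffle(tags)
            per_smell.append(tags)
        # round-robin interleave keeps every contiguous cut class-balanced
        ordered: list[str] = []
        depth = max(len(lst) for lst in per_smell)
        for d in range(depth):
            for lst in per_smell:
                if d < len(lst):
                    ordered.append(lst[d])
        counts = _largest_remainder(len(ordered), fractions)
        if min(counts.values()) == 0 and len(ordered) < len(fractions):
            import warnings

            warnings.warn(
                f"dog {dog!r} has fewer videos ({len(ordered)}) than partitions; "
                "best-effort assignment", stacklevel=2,
            )
        cursor = 0
        for part, k in counts.items():
            for tag in ordered[cursor : cursor + k]:
                assignment[tag] = part
            cursor += k
    return DatasetSplit(assignment=assignment, fractions=fractions, seed=seed)


@dataclass
class TuneConfig:
    """Search-space and budget for in-pipeline hyperparameter tuning."""

    space: dict[str, FloatParam | IntParam] = field(
        default_factory=lambda: {
            "eta": FloatParam(0.02, 0.5, log=True),
            "max_depth": IntParam(2, 6),
        }
    )
    n_trials: int = 20
    sampler: str = "tpe"


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs, in one place."""

    design: DatasetDesign = field(default_factory=DatasetDesign)
    params: GBTParams = field(default_factory=lambda: GBTParams(n_rounds=40, max_depth=3))
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    chunk_len: int = 40
    stride: int | None = None
    track_mode: str = "sequential"
    seed: int = 0
    scopes: tuple[str, ...] = ("aggregated",)
    include_control_aggregated: bool = True
    include_control_per_dog: bool = False
    tuning: TuneConfig | None = None
    out_dir: str | None = None

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {"__class__": type(o).__name__, **o.__dict__}
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return repr(o)

        payload = json.dumps(asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CellResult:
    """Trained/evaluated model of one analysis cell."""

    scope: str
    region: str
    distance_m: float | None
    dog_id: str | None
    matrix: ConfusionMatrix
    normalized: np.ndarray
    metrics: pd.DataFrame
    n_train: int
    n_eval: int
    ensemble: Ensemble | None = None

    @property
    def macro(self) -> dict[str, float | None]:
        return macro_metrics(self.matrix).as_dict()

    def name(self) -> str:
        parts = [self.scope, self.region]
        if self.distance_m is not None:
            parts.append(f"{self.distance_m}m")
        if self.dog_id is not None:
            parts.append(self.dog_id)
        return "_".join(parts)


@dataclass
class Report:
    """Full experiment output: every cell plus provenance."""

    cells: list[CellResult]
    split: DatasetSplit
    provenance: dict
    trial_log: TrialLog | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            macro = cell.macro
            rows.append(
                dict(
                    scope=cell.scope, region=cell.region,
                    distance_m=cell.distance_m, dog_id=cell.dog_id,
                    n_train=cell.n_train, n_eval=cell.n_eval,
                    **{k: (np.nan if v is None else v) for k, v in macro.items()},
                )
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out / "summary_metrics.csv", index=False)
        for cell in self.cells:
            stem = cell.name()
            cell.matrix.to_frame().to_csv(out / f"confusion_{stem}.csv")
            pd.DataFrame(
                cell.normalized,
                index=cell.matrix.class_order, columns=cell.matrix.class_order,
            ).to_csv(out / f"confusion_{stem}_normalized.csv")
            cell.metrics.to_csv(out / f"metrics_{stem}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        if self.trial_log is not None:
            self.trial_log.to_dataframe().to_csv(out / "trials.csv", index=False)


def _eval_partition(fractions: Mapping[str, float]) -> str:
    return "test" if "test" in fractions else "validation"


def train_eval_cell(
    table: pd.DataFrame,
    split: DatasetSplit,
    params: GBTParams,
    scope: str,
    region: str,
    distance_m: float | None,
    dog_id: str | None = None,
    include_control: bool = True,
    shuffle_labels_seed: int | None = None,
) -> CellResult:
    """Train on the train partition of one cell, evaluate held out.

    ``shuffle_labels_seed`` permutes the training labels (a permutation
    null for leakage checks).  Evaluation uses the test partition when
    the split has one, else validation.
    """
    sub = table
    if not include_control:
        sub = sub[sub["smell"] != "control"]
    if sub.empty:
        raise ValueError("analysis cell has no rows")
    train = sub[split.mask(sub, "train")]
    eval_part = _eval_partition(split.fractions)
    held = sub[split.mask(sub, eval_part)]
    if train.empty or held.empty:
        raise ValueError(f"empty train or {eval_part} partition in cell")
    if shuffle_labels_seed is not None:
        rng = np.random.default_rng(shuffle_labels_seed)
        train = train.copy()
        train["smell"] = rng.permutation(train["smell"].to_numpy())
    ensemble = fit(train, params)
    y_pred = predict_labels(ensemble, held)
    class_order = sorted(sub["smell"].unique())
    cm = confusion_matrix(held["smell"].tolist(), y_pred.tolist(), class_order)
    normalized, _ = normalize_rows(cm)
    return CellResult(
        scope=scope, region=region, distance_m=distance_m, dog_id=dog_id,
        matrix=cm, normalized=normalized, metrics=metrics_table(cm),
        n_train=len(train), n_eval=len(held), ensemble=ensemble,
    )


def aggregate_by_region(
    table: pd.DataFrame,
    region: str,
    split: DatasetSplit,
    params: GBTParams,
    distance_m: float | None = None,
    include_control: bool = True,
) -> CellResult:
    """Dog-agnostic cell: pool chunks across dogs within one region.

    With ``distance_m`` ``None`` the two sensing distances are pooled as
    well (the aggregated-confusion-matrix analysis).
    """
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValueError(f"region {region!r} absent from table")
    if sub["dog_id"].nunique() < 2:
        raise ValueError("aggregation requires at least 2 dogs")
    if distance_m is not None:
        sub = sub[sub["distance_m"] == distance_m]
    return train_eval_cell(
        sub, split, params, scope="aggregated", region=region,
        distance_m=distance_m, include_control=include_control,
    )


def simulate_and_featurize(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict[str, tracking.DisplacementTrace], pd.DataFrame]:
    """Stages 1-3: simulate the design, track every video, featurize."""
    videos, manifest = generate_dataset(config.design, config.seed)
    traces = {
        v.video_tag: tracking.track(v, mode=config.track_mode) for v in videos
    }
    table = feat.build_feature_table(
        manifest, traces, chunk_len=config.chunk_len, stride=config.stride
    )
    return manifest, traces, table


def run_experiment(config: ExperimentConfig) -> Report:
    """Full pipeline: simulate -> track -> featurize -> split -> train -> evaluate.

    Deterministic given the config seed.  One model per analysis cell;
    metrics are computed on the held-out partition only.
    """
    manifest, _traces, table = simulate_and_featurize(config)
    split = split_dataset(manifest, config.fractions, seed=config.seed)

    params = config.params
    trial_log = None
    if config.tuning is not None:
        trial_log = _tune_params(table, split, config)
        tuned = {k: v for k, v in trial_log.best_params.items()}
        params = replace(params, **tuned)

    cells: list[CellResult] = []
    regions = list(config.design.regions)
    distances = list(config.design.distances_m)
    for region in regions:
        for dist in distances:
            if "aggregated" in config.scopes:
                sub = table[(table["region"] == region) & (table["distance_m"] == dist)]
                cells.append(
                    train_eval_cell(
                        sub, split, params, scope="aggregated", region=region,
                        distance_m=dist,
                        include_control=config.include_control_aggregated,
                    )
                )
            if "per_dog" in config.scopes:
                for dog in config.design.dogs:
                    sub = table[
                        (table["region"] == region)
                        & (table["distance_m"] == dist)
                        & (table["dog_id"] == dog)
                    ]
                    cells.append(
                        train_eval_cell(
                            sub, split, params, scope="per_dog", region=region,
                            distance_m=dist, dog_id=dog,
                            include_control=config.include_control_per_dog,
                        )
                    )
    provenance = dict(
        config_digest=config.digest(), seed=config.seed,
        schema_hash=feat.schema_hash(), n_videos=len(manifest),
        n_chunks=len(table), fractions=config.fractions,
        gbt_params=params.__dict__,
    )
    report = Report(cells=cells, split=split, provenance=provenance, trial_log=trial_log)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def _tune_params(
    table: pd.DataFrame, split: DatasetSplit, config: ExperimentConfig
) -> TrialLog:
    """Maximize validation macro-F1 over the configured search space."""
    tc = config.tuning
    assert tc is not None
    train = table[split.mask(table, "train")]
    val = table[split.mask(table, "validation")]
    class_order = sorted(table["smell"].unique())

    def objective(params_dict: dict) -> float:
        params = replace(config.params, **params_dict)
        ens = fit(train, params)
        y_pred = predict_labels(ens, val)
        cm = confusion_matrix(val["smell"].tolist(), y_pred.tolist(), class_order)
        f1 = macro_metrics(cm).f1
        return float("nan") if f1 is None else f1

    return tune(
        tc.space, objective, n_trials=tc.n_trials, sampler=tc.sampler,
        direction="maximize", seed=config.seed,
    )
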