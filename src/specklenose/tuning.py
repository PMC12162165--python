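"""Hyperparameter search: random sampling and a TPE-style sampler.

The TPE-style sampler follows the tree-structured Parzen estimator
recipe: after ``n_startup`` random trials the history is split into a
"good" top quantile and a "bad" rest by objective value; each parameter
gets a 1-D Gaussian kernel-density estimate per group; candidates are
drawn from the good density and the one maximizing the good/bad density
ratio is evaluated next.  Parameters are modelled independently (no
multivariate coupling) — a deliberate simplification, so this is
"TPE-style", not a clone of any particular framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FloatParam",
    "IntParam",
    "Trial",
    "TrialLog",
    "tune",
]


@dataclass(frozen=True)
class FloatParam:
    """Continuous domain [low, high]; ``log=True`` samples in log-space."""

    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low must be < high")
        if self.log and self.low <= 0:
            raise ValueError("log-scale domain must be strictly positive")


@dataclass(frozen=True)
class IntParam:
    """Integer domain {low, ..., high} inclusive."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low must be < high")


SearchSpace = Mapping[str, FloatParam | IntParam]


@dataclass
class Trial:
    index: int
    params: dict[str, float | int]
    value: float
    failed: bool = False


@dataclass
class TrialLog:
    """Complete record of one search run."""

    trials: list[Trial]
    direction: str
    sampler: str
    seed: int

    @property
    def best_index(self) -> int:
        ok = [t for t in self.trials if not t.failed]
        if not ok:
            raise ValueError("no successful trials")
        key = (lambda t: t.value) if self.direction == "maximize" else (lambda t: -t.value)
        return max(ok, key=key).index

    @property
    def best_trial(self) -> Trial:
        return self.trials[self.best_index]

    @property
    def best_params(self) -> dict[str, float | int]:
        return dict(self.best_trial.params)

    @property
    def best_value(self) -> float:
        return self.best_trial.value

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(trial=t.index, value=t.value, failed=t.failed, **t.params)
            for t in self.trials
        ]
        return pd.DataFrame(rows)


# -- internal transforms ----------------------------------------------------


def _to_unit(value: float, dom: FloatParam | IntParam) -> float:
    if isinstance(dom, FloatParam) and dom.log:
        return (math.log(value) - math.log(dom.low)) / (math.log(dom.high) - math.log(dom.low))
    return (value - dom.low) / (dom.high - dom.low)


def _from_unit(u: float, dom: FloatParam | IntParam) -> float | int:
    u = min(max(u, 0.0), 1.0)
    if isinstance(dom, IntParam):
        return int(round(dom.low + u * (dom.high - dom.low)))
    if dom.log:
        return float(math.exp(math.log(dom.low) + u * (math.log(dom.high) - math.log(dom.low))))
    return float(dom.low + u * (dom.high - dom.low))


def _sample_random(space: SearchSpace, rng: np.random.Generator) -> dict:
    return {name: _from_unit(rng.uniform(), dom) for name, dom in space.items()}


def _kde_logpdf(x: float, centers: np.ndarray, bandwidth: float) -> float:
    """Log density of a Gaussian KDE augmented with one wide prior kernel.

    The prior kernel (center 0.5, bandwidth 1 in unit coordinates) keeps
    both densities proper over the whole domain and preserves a floor of
    exploration, mirroring the prior weight of standard TPE samplers.
    """
    centers = np.append(centers, 0.5)
    bws = np.full(len(centers), bandwidth)
    bws[-1] = 1.0
    z = (x - centers) / bws
    log_k = -0.5 * z**2 - np.log(bws * math.sqrt(2 * math.pi))
    m = log_k.max()
    return float(m + math.log(np.exp(log_k - m).mean()))


def _bandwidth(centers: np.ndarray) -> float:
    n = len(centers)
    scale = float(centers.std())
    bw = 1.06 * scale * n ** (-1 / 5) if scale > 0 else 0.0
    # floor at 10% of the (unit-scaled) domain: narrower kernels let the
    # sampler collapse onto near-duplicate incumbents and stop exploring
    return max(bw, 0.1)


def _sample_tpe(
    space: SearchSpace,
    history: list[Trial],
    rng: np.random.Generator,
    direction: str,
    good_fraction: float,
    n_candidates: int,
) -> dict:
    ok = [t for t in history if not t.failed]
    values = np.array([t.value for t in ok])
    order = np.argsort(-values if direction == "maximize" else values, kind="stable")
    n_good = max(1, math.ceil(good_fraction * len(ok)))
    good = [ok[i] for i in order[:n_good]]
    bad = [ok[i] for i in order[n_good:]] or good
    # draw joint candidate vectors from the per-parameter good mixtures
    # (each including the wide prior kernel, so a fraction of candidates
    # always explores globally), then keep the vector with the largest
    # summed log density ratio log l(x) - log g(x)
    names = list(space)
    cand = np.empty((n_candidates, len(names)))
    ratio = np.zeros(n_candidates)
    for k, name in enumerate(names):
        dom = space[name]
        good_u = np.array([_to_unit(t.params[name], dom) for t in good])
        bad_u = np.array([_to_unit(t.params[name], dom) for t in bad])
        bw_g = _bandwidth(good_u)
        bw_b = _bandwidth(bad_u)
        kernel_idx = rng.integers(0, len(good_u) + 1, size=n_candidates)
        centers = np.append(good_u, 0.5)[kernel_idx]
        widths = np.where(kernel_idx < len(good_u), bw_g, 1.0)
        cand[:, k] = np.clip(
            centers + rng.normal(0.0, 1.0, size=n_candidates) * widths, 0.0, 1.0
        )
        ratio += [
            _kde_logpdf(c, good_u, bw_g) - _kde_logpdf(c, bad_u, bw_b)
            for c in cand[:, k]
        ]
    winner = cand[int(np.argmax(ratio))]
    return {
        name: _from_unit(float(winner[k]), space[name]) for k, name in enumerate(names)
    }


def tune(
    space: SearchSpace,
    objective: Callable[[dict], float],
    n_trials: int,
    sampler: str = "tpe",
    direction: str = "maximize",
    seed: int = 0,
    n_startup: int = 10,
    good_fraction: float = 0.25,
    n_candidates: int = 24,
) -> TrialLog:
    """Run a hyperparameter search and return the full trial log.

    ``objective`` maps a parameter dict to a scalar score; a non-finite
    return marks the trial failed and excludes it from the density
    models and from the best-trial selection.  Fully reproducible for a
    fixed seed.
    """
    if not space:
        raise ValueError("search space is empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler not in ("random", "tpe"):
        raise ValueError(f"unknown sampler {sampler!r}")
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    log = TrialLog(trials=[], direction=direction, sampler=sampler, seed=seed)
    for i in range(n_trials):
        use_tpe = (
            sampler == "tpe"
            and i >= n_startup
            and sum(not t.failed for t in log.trials) >= 2
        )
        params = (
            _sample_tpe(space, log.trials, rng, direction, good_fraction, n_candidates)
            if use_tpe
            else _sample_random(space, rng)
        )
        value = float(objective(dict(params)))
        failed = not math.isfinite(value)
        log.trials.append(Trial(index=i, params=params, value=value, failed=failed))
    return log
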