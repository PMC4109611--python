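"""ROI and subsystem predictability measures and their scaling over k.

Five seed-level measures (all in bits, estimated under the Gaussian
assumption from the pooled activity matrix):

- Seed-Neighbor MI   I(i; n_i(k)) — seed vs its k-th ranked neighbor;
- Seed-Subsystem MI  I(i; S_i(k)\\i) — seed vs the rest of its size-k
  subsystem;
- Total MI           I(i; V\\i) — seed vs the whole rest of the hemisphere
  (metric-independent);
- Seed-Environment MI I(i; E_i(k)) — seed vs everything outside its
  subsystem;
- Coupling Range — the first subsystem size at which Seed-Environment MI
  drops below a bit threshold (0.3 bits by default): the spatial reach
  of a seed's functional coupling.

Two subsystem-level measures, normalized per ROI (bits/ROI):

- Subsystem Integration    TC(S_i(k)) / k;
- Subsystem-Environment MI I(S_i(k); E_i(k)) / k.

Scaling curves evaluate a measure per seed across subsystem sizes and
summarize across seeds by mean and quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .data import ActivityMatrix
from .entropy import EntropyCalculator, Estimator
from .graphs import NeighborRanking, build_subsystem

__all__ = [
    "seed_neighbor_mi",
    "seed_subsystem_mi",
    "total_mi",
    "seed_environment_mi",
    "coupling_range",
    "subsystem_integration_per_roi",
    "subsystem_environment_mi_per_roi",
    "scan_curves",
    "coupling_range_per_seed",
    "ScalingCurve",
    "MEASURES",
]


def _calculator(
    x: ActivityMatrix | EntropyCalculator, estimator: Estimator
) -> EntropyCalculator:
    if isinstance(x, EntropyCalculator):
        if x.estimator != estimator:
            raise ValueError(
                f"calculator uses estimator {x.estimator!r}, requested {estimator!r}"
            )
        return x
    return EntropyCalculator(x, estimator=estimator)


def seed_neighbor_mi(
    seed: int,
    k: int,
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """I(i; n_i(k)): pairwise MI between a seed and its k-th ranked neighbor."""
    calc = _calculator(x, estimator)
    return calc.mutual_information([seed], [ranking.neighbor(seed, k)])


def seed_subsystem_mi(
    seed: int,
    k: int,
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """I(i; S_i(k)\\i): how well the subsystem collectively predicts the seed."""
    if k < 2:
        raise ValueError("seed_subsystem_mi needs k >= 2 (non-empty S\\i)")
    sub = build_subsystem(ranking, seed, k)
    calc = _calculator(x, estimator)
    return calc.mutual_information([seed], [r for r in sub.members if r != seed])


def total_mi(
    seed: int,
    hemisphere_rois: Iterable[int],
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """I(i; V\\i): total prediction available about the seed from its hemisphere."""
    others = [r for r in hemisphere_rois if r != seed]
    if not others:
        raise ValueError("hemisphere must contain at least 2 ROIs")
    calc = _calculator(x, estimator)
    return calc.mutual_information([seed], others)


def seed_environment_mi(
    seed: int,
    k: int,
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """I(i; E_i(k)): how well the environment predicts the seed.

    At k=1 the subsystem is the seed alone, so this equals Total MI.
    """
    sub = build_subsystem(ranking, seed, k)
    if not sub.environment:
        raise ValueError(f"empty environment at k={k} for seed {seed}")
    calc = _calculator(x, estimator)
    return calc.mutual_information([seed], list(sub.environment))


def coupling_range(
    values: Sequence[float], threshold: float = 0.3
) -> tuple[int, bool]:
    """First k at which a Seed-Environment MI curve drops below threshold.

    ``values`` must be the curve on the contiguous grid k = 1, 2, ...
    Returns (k, censored): the smallest k with value < threshold, or the
    largest k on the grid with ``censored=True`` if the curve never
    crosses.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty coupling curve")
    below = np.flatnonzero(values < threshold)
    if below.size:
        return int(below[0] + 1), False
    return int(values.size), True


def subsystem_integration_per_roi(
    seed: int,
    k: int,
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """TC(S_i(k)) / k: size-normalized integration of the seed's subsystem."""
    if k < 2:
        raise ValueError("subsystem integration needs k >= 2")
    sub = build_subsystem(ranking, seed, k)
    calc = _calculator(x, estimator)
    return calc.total_correlation(list(sub.members)) / k


def subsystem_environment_mi_per_roi(
    seed: int,
    k: int,
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> float:
    """I(S_i(k); E_i(k)) / k: size-normalized subsystem-environment coupling."""
    sub = build_subsystem(ranking, seed, k)
    if not sub.environment:
        raise ValueError(f"empty environment at k={k} for seed {seed}")
    calc = _calculator(x, estimator)
    return calc.mutual_information(list(sub.members), list(sub.environment)) / k


_MEASURE_FUNCS: dict[str, Callable] = {
    "seed_neighbor_mi": seed_neighbor_mi,
    "seed_subsystem_mi": seed_subsystem_mi,
    "seed_environment_mi": seed_environment_mi,
    "subsystem_integration_per_roi": subsystem_integration_per_roi,
    "subsystem_environment_mi_per_roi": subsystem_environment_mi_per_roi,
}
MEASURES = tuple(_MEASURE_FUNCS)


@dataclass(frozen=True)
class ScalingCurve:
    """A measure evaluated per seed across subsystem sizes k.

    ``values`` is a tidy frame (measure, metric, seed, k, value);
    ``summary`` carries mean/Q1/Q3 across seeds per k.
    """

    measure: str
    metric: str
    values: pd.DataFrame
    summary: pd.DataFrame

    def seed_curve(self, seed: int) -> pd.Series:
        sub = self.values[self.values["seed"] == seed].sort_values("k")
        return pd.Series(sub["value"].to_numpy(), index=sub["k"].to_numpy())


def scan_curves(
    measure: str,
    metric: str,
    k_grid: Sequence[int],
    seeds: Sequence[int],
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    estimator: Estimator = "umvu",
) -> ScalingCurve:
    """Evaluate one measure for every (seed, k) and summarize across seeds.

    A shared entropy cache is used across seeds and sizes, since joint
    environment entropies at large k dominate the cost and recur.
    Per-seed failures are re-raised with the offending seed and k named.
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    k_grid = list(k_grid)
    if any(k2 <= k1 for k1, k2 in zip(k_grid, k_grid[1:])):
        raise ValueError("k grid must be strictly increasing")
    calc = _calculator(x, estimator)
    func = _MEASURE_FUNCS[measure]
    rows = []
    for seed in seeds:
        for k in k_grid:
            try:
                value = func(seed, k, ranking, calc, estimator)
            except Exception as exc:
                raise RuntimeError(
                    f"{measure} failed for seed {seed}, k={k}: {exc}"
                ) from exc
            rows.append({"measure": measure, "metric": metric,
                         "seed": seed, "k": k, "value": value})
    values = pd.DataFrame(rows)
    summary = (
        values.groupby("k")["value"]
        .agg(mean="mean", q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    summary.insert(0, "metric", metric)
    summary.insert(0, "measure", measure)
    return ScalingCurve(measure, metric, values, summary)


def coupling_range_per_seed(
    seeds: Sequence[int],
    ranking: NeighborRanking,
    x: ActivityMatrix | EntropyCalculator,
    threshold: float = 0.3,
    estimator: Estimator = "umvu",
    k_max: int | None = None,
) -> pd.DataFrame:
    """Coupling Range per seed: scan Seed-Environment MI on k = 1..k_max.

    ``k_max`` defaults to hemisphere size - 1 (the largest k with a
    non-empty environment).  Returns a frame (seed, coupling_range,
    censored).
    """
    calc = _calculator(x, estimator)
    rows = []
    for seed in seeds:
        limit = len(ranking.order[seed]) if k_max is None else k_max
        curve = [
            seed_environment_mi(seed, k, ranking, calc, estimator)
            for k in range(1, limit + 1)
        ]
        rng, censored = coupling_range(curve, threshold)
        rows.append({"seed": seed, "coupling_range": rng, "censored": censored})
    return pd.DataFrame(rows)
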