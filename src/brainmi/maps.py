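"""Structure-function maps: pairwise-MI distance binning and the
correlation between Seed-Environment MI and long-range efficiency.

The binned map averages pairwise MI over intra-hemispheric ROI pairs in
a 2-D grid of equal-width Euclidean x connectome distance bins,
summarizing how functional coupling decays with physical and structural
separation.  The efficiency correlation asks, scale by scale, whether
the seeds best coupled to their distant (Euclidean-environment) ROIs are
also the seeds most efficiently reachable from them over the connectome
— computed per hemisphere and averaged between hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .data import ActivityMatrix, RoiTable
from .entropy import EntropyCalculator, Estimator
from .graphs import DistanceMatrix, NeighborRanking, build_subsystem, long_range_efficiency
from .measures import seed_environment_mi

__all__ = [
    "pairwise_mi_matrix",
    "binned_mi_map",
    "efficiency_mi_correlation",
    "BinnedMiMap",
]


def pairwise_mi_matrix(
    x: ActivityMatrix,
    rois: RoiTable,
    estimator: Estimator = "umvu",
) -> pd.DataFrame:
    """MI (bits) for every intra-hemispheric ROI pair.

    Returns a symmetric ROI x ROI frame indexed by roi_id; the diagonal
    and inter-hemispheric entries are NaN (undefined, not zero).
    """
    calc = EntropyCalculator(x, estimator=estimator)
    ids = rois.roi_ids
    hemi = rois.hemispheres
    n = len(ids)
    mi = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            if hemi[a] != hemi[b]:
                continue
            val = calc.mutual_information([ids[a]], [ids[b]])
            mi[a, b] = mi[b, a] = val
    return pd.DataFrame(mi, index=ids, columns=ids)


@dataclass(frozen=True)
class BinnedMiMap:
    """Mean pairwise MI per (Euclidean bin, connectome bin) cell.

    Empty cells are NaN (flagged, never zero-filled); ``counts`` records
    the pairs per cell and sums to the number of intra-hemispheric pairs
    with finite distances on both axes.  ``excluded_infinite`` counts
    pairs dropped for an infinite connectome distance.
    """

    euclid_edges: np.ndarray
    connectome_edges: np.ndarray
    mean_mi: np.ndarray
    counts: np.ndarray
    euclid_marginal: np.ndarray
    connectome_marginal: np.ndarray
    excluded_infinite: int


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open equal-width binning: a value on an interior edge joins the
    higher bin; the global maximum closes the last bin."""
    n_bins = len(edges) - 1
    width = edges[-1] - edges[0]
    if width == 0:
        return np.zeros(len(values), dtype=int)
    idx = np.floor((values - edges[0]) / (width / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def binned_mi_map(
    mi: pd.DataFrame,
    d_euc: DistanceMatrix,
    d_con: DistanceMatrix,
    n_bins: int = 50,
) -> BinnedMiMap:
    """Bin intra-hemispheric pairwise MI on Euclidean x connectome distance.

    Bin edges span the observed min..max of each axis with ``n_bins``
    equal-width bins; pairs with an infinite connectome distance are
    excluded from the grid and counted separately.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ids = mi.index.to_numpy()
    pos_e = {rid: i for i, rid in enumerate(d_euc.roi_ids)}
    pos_c = {rid: i for i, rid in enumerate(d_con.roi_ids)}
    pairs_mi, pairs_de, pairs_dc = [], [], []
    excluded = 0
    arr = mi.to_numpy()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            val = arr[a, b]
            if np.isnan(val):
                continue  # inter-hemispheric or diagonal: undefined
            de = d_euc.d[pos_e[ids[a]], pos_e[ids[b]]]
            dc = d_con.d[pos_c[ids[a]], pos_c[ids[b]]]
            if not np.isfinite(dc) or not np.isfinite(de):
                excluded += 1
                continue
            pairs_mi.append(val)
            pairs_de.append(de)
            pairs_dc.append(dc)
    if not pairs_mi:
        raise ValueError("no intra-hemispheric pairs with finite distances")
    pairs_mi = np.asarray(pairs_mi)
    pairs_de = np.asarray(pairs_de)
    pairs_dc = np.asarray(pairs_dc)
    e_edges = np.linspace(pairs_de.min(), pairs_de.max(), n_bins + 1)
    c_edges = np.linspace(pairs_dc.min(), pairs_dc.max(), n_bins + 1)
    ei = _bin_index(pairs_de, e_edges)
    ci = _bin_index(pairs_dc, c_edges)
    total = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(total, (ei, ci), pairs_mi)
    np.add.at(counts, (ei, ci), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)

    def marginal(idx: np.ndarray) -> np.ndarray:
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                out[b] = pairs_mi[mask].mean()
        return out

    return BinnedMiMap(
        euclid_edges=e_edges,
        connectome_edges=c_edges,
        mean_mi=mean,
        counts=counts,
        euclid_marginal=marginal(ei),
        connectome_marginal=marginal(ci),
        excluded_infinite=excluded,
    )


def efficiency_mi_correlation(
    k_grid,
    rois: RoiTable,
    x: ActivityMatrix,
    euclid_ranking: NeighborRanking,
    distance_matrices: dict[str, DistanceMatrix],
    estimator: Estimator = "umvu",
) -> pd.DataFrame:
    """Pearson r between Seed-Environment MI and long-range efficiency.

    For each subsystem size k: Seed-Environment MI is computed with
    Euclidean environments; long-range efficiency of each seed to that
    same Euclidean environment is computed under each metric's shortest
    paths.  r is computed across seeds separately per hemisphere and the
    two hemispheric values averaged.  Cells where either vector is
    constant are NaN (r undefined) and flagged in the output.

    Returns a frame (k, metric, r_left, r_right, r_mean).
    """
    calc = EntropyCalculator(x, estimator=estimator)
    rows = []
    hemi_seeds = {h: rois.hemisphere_ids(h) for h in ("L", "R")}
    for k in k_grid:
        env_mi: dict[str, np.ndarray] = {}
        envs: dict[str, list] = {}
        for h, seeds in hemi_seeds.items():
            mis, env_list = [], []
            for seed in seeds:
                sub = build_subsystem(euclid_ranking, seed, k)
                env_list.append(sub.environment)
                mis.append(seed_environment_mi(seed, k, euclid_ranking, calc, estimator))
            env_mi[h] = np.asarray(mis)
            envs[h] = env_list
        for metric, dist in distance_matrices.items():
            r_by_hemi = {}
            for h, seeds in hemi_seeds.items():
                if len(seeds) < 3:
                    raise ValueError("need >= 3 seeds per hemisphere for a correlation")
                eff = np.array(
                    [
                        long_range_efficiency(seed, env, dist)
                        for seed, env in zip(seeds, envs[h])
                    ]
                )
                if np.ptp(eff) == 0 or np.ptp(env_mi[h]) == 0:
                    r_by_hemi[h] = np.nan
                else:
                    r_by_hemi[h] = pearsonr(env_mi[h], eff).statistic
            vals = [r_by_hemi["L"], r_by_hemi["R"]]
            finite = [v for v in vals if np.isfinite(v)]
            rows.append(
                {
                    "k": k,
                    "metric": metric,
                    "r_left": vals[0],
                    "r_right": vals[1],
                    "r_mean": np.mean(finite) if finite else np.nan,
                }
            )
    return pd.DataFrame(rows)
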