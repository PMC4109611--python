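"""Distance metrics, neighbor rankings, subsystems, and efficiency.

Three metrics order each region's same-hemisphere neighbors:

- *euclidean*: straight-line distance between ROI centroids (mm);
- *connectome*: shortest-path distance on the structural graph with edge
  lengths 1/NOF (high fiber count = short dissimilarity);
- *randomized*: the same construction on a degree-preserving
  (Maslov-Sneppen) rewiring of the connectome, a null model that keeps
  the density, the degree sequence and the NOF weight distribution but
  destroys the spatial/topological organization.

A seed's size-k subsystem S_i(k) is the seed plus its k-1 nearest
neighbors under a chosen metric; the environment E_i(k) is the rest of
the hemisphere.  Long-range efficiency of a seed is the mean inverse
shortest-path distance to its Euclidean-environment ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import squareform, pdist

from .data import RoiTable, StructuralConnectome

__all__ = [
    "DistanceMatrix",
    "NeighborRanking",
    "Subsystem",
    "euclidean_distances",
    "dissimilarity_from_nof",
    "shortest_path_distances",
    "connectome_distances",
    "rewire_connectome",
    "rank_neighbors",
    "build_subsystem",
    "long_range_efficiency",
    "METRICS",
]

logger = logging.getLogger(__name__)

Metric = Literal["euclidean", "connectome", "randomized"]
METRICS: tuple[Metric, ...] = ("euclidean", "connectome", "randomized")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric ROI x ROI distance matrix; +inf marks unreachable pairs."""

    metric: str
    d: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "roi_ids", np.asarray(self.roi_ids))

    def lookup(self, a: int, b: int) -> float:
        pos = {rid: i for i, rid in enumerate(self.roi_ids)}
        return float(self.d[pos[a], pos[b]])


@dataclass(frozen=True)
class NeighborRanking:
    """Per-seed ordered neighbor lists n_i(1), n_i(2), ... (same hemisphere).

    ``order[seed]`` lists the seed's same-hemisphere neighbors by
    increasing distance; ties broken by ascending roi_id, unreachable
    (infinite-distance) neighbors last.  Rankings need not be symmetric:
    j being i's kth neighbor does not make i the kth neighbor of j.
    """

    metric: str
    order: dict[int, np.ndarray]
    distances: dict[int, np.ndarray]
    tie_break: str = "ascending roi_id"

    def neighbor(self, seed: int, k: int) -> int:
        """The k-th ranked neighbor n_i(k), k starting at 1."""
        ranked = self.order[seed]
        if not 1 <= k <= len(ranked):
            raise ValueError(f"rank k={k} out of range 1..{len(ranked)} for seed {seed}")
        return int(ranked[k - 1])


@dataclass(frozen=True)
class Subsystem:
    """Seed-centered ROI set S_i(k) and its environment E_i(k)."""

    seed: int
    k: int
    members: tuple[int, ...]
    environment: tuple[int, ...]


def euclidean_distances(rois: RoiTable) -> DistanceMatrix:
    """Pairwise centroid distances (mm), all ROI pairs."""
    d = squareform(pdist(rois.centroids))
    return DistanceMatrix("euclidean", d, rois.roi_ids)


def dissimilarity_from_nof(connectome: StructuralConnectome) -> np.ndarray:
    """Edge-length matrix 1/NOF; entries without a fiber connection are 0.

    A zero entry means *no edge* (scipy.sparse.csgraph convention), not a
    zero-length edge.
    """
    w = connectome.weights
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return lengths


def shortest_path_distances(
    lengths: np.ndarray, roi_ids: np.ndarray, metric: str = "connectome"
) -> DistanceMatrix:
    """All-pairs shortest paths on a nonnegative edge-length matrix.

    Unreachable pairs (including everything across hemispheres, since the
    inter-hemispheric block carries no edges) come out as +inf.
    """
    if (np.asarray(lengths) < 0).any():
        raise ValueError("edge lengths must be nonnegative")
    d = dijkstra(lengths, directed=False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(metric, d, np.asarray(roi_ids))


def connectome_distances(
    connectome: StructuralConnectome, metric: str = "connectome"
) -> DistanceMatrix:
    """Shortest-path distances on the 1/NOF dissimilarity graph."""
    return shortest_path_distances(
        dissimilarity_from_nof(connectome), connectome.roi_ids, metric
    )


def _hemisphere_blocks(rois: RoiTable) -> dict[str, np.ndarray]:
    return {h: np.flatnonzero(rois.hemispheres == h) for h in ("L", "R")}


def rewire_connectome(
    connectome: StructuralConnectome,
    rois: RoiTable,
    n_swap_multiple: int = 10,
    rng_seed: int = 0,
) -> StructuralConnectome:
    """Degree-preserving (Maslov-Sneppen) rewiring, per hemisphere.

    Repeated double-edge swaps (a-b, c-d) -> (a-d, c-b) in which each edge
    carries its NOF weight; swaps creating self-loops or multi-edges are
    rejected.  The degree sequence, edge count, and weight multiset are
    exactly preserved; the inter-hemispheric block stays zero.  The
    default budget is ``n_swap_multiple`` x (edge count) attempted swaps
    per hemisphere; the acceptance rate is logged.
    """
    if n_swap_multiple < 0:
        raise ValueError("n_swap_multiple must be >= 0")
    rng = np.random.default_rng(rng_seed)
    w = connectome.weights.copy()
    for hemi, idx in _hemisphere_blocks(rois).items():
        if len(idx) == 0:
            continue
        sub = w[np.ix_(idx, idx)]
        iu, ju = np.triu_indices_from(sub, k=1)
        present = sub[iu, ju] > 0
        edges = list(zip(iu[present].tolist(), ju[present].tolist()))
        weights = sub[iu[present], ju[present]].tolist()
        m = len(edges)
        if m < 2 or n_swap_multiple == 0:
            continue
        edge_set = {e for e in edges}
        attempts = n_swap_multiple * m
        accepted = 0
        for _ in range(attempts):
            e1, e2 = rng.choice(m, size=2, replace=False)
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.random() < 0.5:
                c, d = d, c
            # proposed: a-d and c-b
            if len({a, b, c, d}) < 4:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            accepted += 1
        logger.info(
            "rewiring hemisphere %s: %d/%d swaps accepted", hemi, accepted, attempts
        )
        new_sub = np.zeros_like(sub)
        for (a, b), wt in zip(edges, weights):
            new_sub[a, b] = wt
            new_sub[b, a] = wt
        w[np.ix_(idx, idx)] = new_sub
    return StructuralConnectome(w, connectome.roi_ids)


def rank_neighbors(dist: DistanceMatrix, rois: RoiTable) -> NeighborRanking:
    """Order each seed's same-hemisphere neighbors by increasing distance.

    Ties broken by ascending roi_id; unreachable neighbors (distance
    +inf) ranked last, themselves ordered by roi_id.
    """
    pos = {rid: i for i, rid in enumerate(dist.roi_ids)}
    order: dict[int, np.ndarray] = {}
    distances: dict[int, np.ndarray] = {}
    for hemi in ("L", "R"):
        hemi_ids = rois.hemisphere_ids(hemi)
        if len(hemi_ids) == 0:
            continue
        hemi_pos = np.array([pos[r] for r in hemi_ids])
        for seed, seed_pos in zip(hemi_ids, hemi_pos):
            others = hemi_ids[hemi_ids != seed]
            other_pos = hemi_pos[hemi_ids != seed]
            d = dist.d[seed_pos, other_pos]
            # lexsort: primary key distance, secondary roi_id; inf sorts last
            perm = np.lexsort((others, d))
            order[int(seed)] = others[perm]
            distances[int(seed)] = d[perm]
    return NeighborRanking(dist.metric, order, distances)


def build_subsystem(ranking: NeighborRanking, seed: int, k: int) -> Subsystem:
    """S_i(k) = seed + its k-1 nearest neighbors; E_i(k) = the rest."""
    ranked = ranking.order[seed]
    hemi_size = len(ranked) + 1
    if not 1 <= k <= hemi_size:
        raise ValueError(f"k={k} out of range 1..{hemi_size} for seed {seed}")
    members = (seed, *map(int, ranked[: k - 1]))
    environment = tuple(map(int, ranked[k - 1:]))
    return Subsystem(seed=seed, k=k, members=members, environment=environment)


def long_range_efficiency(
    seed: int, euclid_env: Iterable[int], dist: DistanceMatrix
) -> float:
    """Mean inverse shortest-path distance from a seed to its Euclidean
    environment, under any metric's distance matrix.

    Unreachable ROIs (infinite distance) contribute 0.
    """
    env = list(euclid_env)
    if not env:
        raise ValueError("environment is empty")
    pos = {rid: i for i, rid in enumerate(dist.roi_ids)}
    d = dist.d[pos[seed], [pos[j] for j in env]]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, np.where(d == 0, np.inf, 0.0))
    # a zero-distance environment ROI would make efficiency infinite;
    # that only happens with duplicated centroids on the euclidean metric
    return float(np.mean(inv))
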