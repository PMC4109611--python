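"""Subsystem community detection (integration/segregation trade-off).

Connectome subsystems that are jointly high (strictly above the
hemisphere median, i.e. upper 50th percentile) in both Subsystem
Integration and Subsystem-Environment MI are selected; their pairwise
membership-overlap matrix is clustered with Louvain modularity
maximization; and each ROI appearing in at least one selected subsystem
is assigned to the community in which it appears most often.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import Subsystem

__all__ = [
    "select_subsystems",
    "overlap_matrix",
    "detect_communities",
    "assign_rois",
    "OverlapMatrix",
]


def select_subsystems(
    integration: pd.Series,
    env_mi: pd.Series,
    percentile: float = 50.0,
) -> list[int]:
    """Seeds whose subsystems are strictly above the given percentile on
    both measures.

    ``integration`` and ``env_mi`` are per-seed values (index = seed
    roi_id) for one hemisphere at a fixed subsystem size.  With the
    default percentile of 50 this keeps subsystems strictly above the
    median of each measure; boundary values are excluded, so an
    all-identical measure selects nothing.
    """
    if not integration.index.equals(env_mi.index):
        raise ValueError("integration and env_mi must cover the same seeds")
    ti = np.percentile(integration.to_numpy(), percentile)
    te = np.percentile(env_mi.to_numpy(), percentile)
    mask = (integration > ti) & (env_mi > te)
    return [int(s) for s in integration.index[mask]]


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise fraction of shared ROIs between equal-size subsystems.

    Entries are |members_a ∩ members_b| / k in [0, 1]; the diagonal is
    zeroed so self-overlap cannot inflate modularity during clustering.
    """

    subsystem_ids: np.ndarray
    overlap: np.ndarray


def overlap_matrix(subsystems: list[Subsystem]) -> OverlapMatrix:
    """Overlap fractions between all pairs of (same-hemisphere, equal-k)
    subsystems; diagonal set to 0."""
    if not subsystems:
        raise ValueError("no subsystems")
    k = subsystems[0].k
    if any(s.k != k for s in subsystems):
        raise ValueError("subsystems must share the same size k")
    member_sets = [set(s.members) for s in subsystems]
    n = len(subsystems)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            frac = len(member_sets[a] & member_sets[b]) / k
            mat[a, b] = mat[b, a] = frac
    ids = np.array([s.seed for s in subsystems])
    return OverlapMatrix(ids, mat)


def detect_communities(overlap: OverlapMatrix, rng_seed: int = 0) -> dict[int, int]:
    """Louvain modularity partition of the weighted overlap graph.

    Returns subsystem seed -> community id, with community ids 0, 1, ...
    ordered by decreasing community size (ties by smallest member seed).
    Subsystems with zero overlap to everything become singleton
    communities.
    """
    ids = overlap.subsystem_ids
    if len(ids) == 0:
        raise ValueError("empty overlap matrix")
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in ids)
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            w = overlap.overlap[a, b]
            if w > 0:
                g.add_edge(int(ids[a]), int(ids[b]), weight=float(w))
    parts = nx.community.louvain_communities(g, weight="weight", seed=rng_seed)
    parts = sorted(parts, key=lambda c: (-len(c), min(c)))
    return {node: cid for cid, comm in enumerate(parts) for node in comm}


def assign_rois(
    subsystem_communities: dict[int, int],
    subsystems: list[Subsystem],
    all_rois: list[int] | None = None,
) -> pd.DataFrame:
    """ROI-level community assignment by majority membership.

    Each ROI appearing in >= 1 selected subsystem is assigned to the
    community in which it appears most often (ties broken by lowest
    community id); other ROIs are explicitly unassigned (community -1).

    Returns a frame (roi_id, community, n_subsystems).
    """
    by_seed = {s.seed: s for s in subsystems}
    counts: dict[int, dict[int, int]] = {}
    for seed, community in subsystem_communities.items():
        for roi in by_seed[seed].members:
            counts.setdefault(roi, {}).setdefault(community, 0)
            counts[roi][community] += 1
    rois = sorted(counts) if all_rois is None else list(all_rois)
    rows = []
    for roi in rois:
        per_comm = counts.get(roi)
        if not per_comm:
            rows.append({"roi_id": roi, "community": -1, "n_subsystems": 0})
            continue
        best = min(per_comm.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        rows.append(
            {
                "roi_id": roi,
                "community": int(best),
                "n_subsystems": int(sum(per_comm.values())),
            }
        )
    return pd.DataFrame(rows)
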