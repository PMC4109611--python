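"""Canonical synthetic study conditions.

One function assembles the full synthetic dataset used throughout the
validation suite: mirrored two-hemisphere geometry, a distance-dependent
connectome, functional hubs planted at the structurally most central
regions, the ground-truth covariance, and a pooled activity matrix.
Sub-seeds for the independent random stages (geometry, connectome,
sampling) are derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ActivityMatrix, RoiTable, StructuralConnectome
from .preprocess import pool_subjects
from .simulate import (
    CovarianceModel,
    generate_connectome,
    generate_covariance,
    generate_roi_geometry,
    sample_subjects,
    structural_hubs,
)

__all__ = ["SyntheticStudy", "make_synthetic_study"]


@dataclass(frozen=True)
class SyntheticStudy:
    rois: RoiTable
    connectome: StructuralConnectome
    covariance: CovarianceModel
    pooled: ActivityMatrix
    hubs: list[int]


def make_synthetic_study(
    rng_seed: int,
    n_per_hemisphere: int = 20,
    extent: float = 100.0,
    density: float = 0.3,
    decay_length: float = 60.0,
    spatial_scale: float = 30.0,
    structural_gain: float = 0.6,
    n_hubs_per_hemisphere: int = 2,
    n_subjects: int = 1,
    n_samples: int = 5000,
) -> SyntheticStudy:
    """Generate the default synthetic study dataset.

    The defaults give 20 ROIs per hemisphere in a 100 mm box, a
    30%-density connectome with 60 mm fiber-length decay, spatial
    functional coupling on a 30 mm scale plus connectome-mediated
    coupling, two strength-ranked hub ROIs per hemisphere, and a pooled
    5,000-sample activity matrix.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(3) % (2**31)
    rois = generate_roi_geometry(n_per_hemisphere, extent, rng_seed=int(seeds[0]))
    conn = generate_connectome(
        rois, density=density, decay_length=decay_length, rng_seed=int(seeds[1])
    )
    hubs = structural_hubs(conn, rois, n_hubs_per_hemisphere)
    cov = generate_covariance(
        rois,
        conn,
        spatial_scale=spatial_scale,
        structural_gain=structural_gain,
        hubs=hubs,
    )
    subjects = sample_subjects(cov, n_subjects, n_samples, rng_seed=int(seeds[2]))
    pooled = pool_subjects(subjects)
    return SyntheticStudy(rois, conn, cov, pooled, hubs)
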