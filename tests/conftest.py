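import numpy as np
import pandas as pd
import pytest

import brainmi as bm
from brainmi.entropy import EntropyCalculator
from brainmi import graphs


def make_roi_table(centroids, hemispheres, ids=None):
    ids = list(range(len(centroids))) if ids is None else ids
    return bm.RoiTable(
        pd.DataFrame(
            {
                "roi_id": ids,
                "hemisphere": hemispheres,
                "x": [c[0] for c in centroids],
                "y": [c[1] for c in centroids],
                "z": [c[2] for c in centroids],
                "area_label": ["a"] * len(centroids),
            }
        )
    )


@pytest.fixture(scope="session")
def small_world():
    """12-ROI fixture (6 per hemisphere) with ground-truth covariance and a
    comfortably large pooled sample for exact-identity and monotonicity
    checks."""
    rois = bm.generate_roi_geometry(6, extent=80.0, rng_seed=11)
    conn = bm.generate_connectome(rois, density=0.5, decay_length=60.0, rng_seed=12)
    cov = bm.generate_covariance(rois, conn, spatial_scale=30.0, structural_gain=0.6)
    pooled = bm.pool_subjects(bm.sample_subjects(cov, 1, 2000, rng_seed=13))
    return {"rois": rois, "connectome": conn, "cov": cov, "pooled": pooled}


@pytest.fixture(scope="session")
def small_rankings(small_world):
    dists = {
        "euclidean": graphs.euclidean_distances(small_world["rois"]),
        "connectome": graphs.connectome_distances(small_world["connectome"]),
    }
    return {m: graphs.rank_neighbors(d, small_world["rois"]) for m, d in dists.items()}


@pytest.fixture(scope="session")
def small_calcs(small_world):
    return {
        est: EntropyCalculator(small_world["pooled"], estimator=est)
        for est in ("umvu", "plugin")
    }
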