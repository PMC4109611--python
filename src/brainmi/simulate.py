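"""Synthetic ROI geometry, connectome, covariance, and activity generator.

No subject MRI data are deposited with the study this package supports,
so analyses are exercised on synthetic data that reproduces the
statistical structure the measures assume:

- two hemispheres of spatially embedded ROIs (the right hemisphere a
  mirror image of the left, keeping per-hemisphere analyses comparable);
- an intra-hemispheric, distance-dependent weighted connectome with
  integer number-of-fibers (NOF) weights;
- zero-mean stationary Gaussian activity whose covariance combines
  (i) a squared-exponential spatially decaying kernel ("near things are
  more related than distant things"), (ii) connectome-mediated coupling
  so structurally connected pairs are functionally coupled even at long
  range, (iii) designated hub ROIs with extra long-range functional
  links, and (iv) an independent noise floor.

The ground-truth covariance doubles as an analytic oracle: every mutual
information and total correlation has a closed Gaussian form in terms of
log-determinants of its sub-blocks, against which the sample-based
estimators can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .data import ActivityMatrix, RoiTable, StructuralConnectome

__all__ = [
    "CovarianceModel",
    "generate_roi_geometry",
    "generate_connectome",
    "generate_covariance",
    "sample_subjects",
    "structural_hubs",
    "analytic_measure",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class CovarianceModel:
    """Ground-truth ROI covariance with unit marginal variances.

    ``sigma`` is symmetric positive definite with unit diagonal; ``params``
    records the generating kernel parameters (decay length in mm,
    structural gain, hub list, noise floor) and the ridge applied, if any,
    to restore positive definiteness.
    """

    sigma: np.ndarray
    roi_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if not np.allclose(s, s.T):
            raise ValueError("covariance must be symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("covariance must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(s).min())
        if eigmin <= 0:
            raise ValueError(f"covariance not positive definite (min eig {eigmin:g})")
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "roi_ids", np.asarray(self.roi_ids))

    def submatrix(self, roi_set: Iterable[int]) -> np.ndarray:
        pos = {rid: i for i, rid in enumerate(self.roi_ids)}
        idx = [pos[r] for r in roi_set]
        return self.sigma[np.ix_(idx, idx)]


def generate_roi_geometry(
    n_per_hemisphere: int,
    extent: float = 100.0,
    rng_seed: int = 0,
    n_areas: int = 4,
    gap: float = 10.0,
) -> RoiTable:
    """Two mirrored point clouds of ROI centroids, separated along x.

    Left-hemisphere centroids are drawn uniformly in a box of side
    ``extent`` mm offset by ``gap``/2 from the mid-sagittal plane; the
    right hemisphere is the mirror image (x -> -x).  ROIs are grouped
    into ``n_areas`` anatomical-area labels by contiguous index blocks.
    """
    if n_per_hemisphere < 2:
        raise ValueError("need at least 2 ROIs per hemisphere")
    if extent <= 0 or gap < 0:
        raise ValueError("extent must be positive and gap nonnegative")
    rng = np.random.default_rng(rng_seed)
    left = rng.uniform(0.0, extent, size=(n_per_hemisphere, 3))
    left[:, 0] += gap / 2.0
    right = left.copy()
    right[:, 0] *= -1.0
    rows = []
    block = max(1, int(np.ceil(n_per_hemisphere / n_areas)))
    rid = 0
    for hemi, pts in (("L", left), ("R", right)):
        for i, p in enumerate(pts):
            rows.append(
                {
                    "roi_id": rid,
                    "hemisphere": hemi,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                    "area_label": f"{hemi}-area-{i // block + 1}",
                }
            )
            rid += 1
    return RoiTable(pd.DataFrame(rows))


def generate_connectome(
    rois: RoiTable,
    density: float = 0.3,
    decay_length: float = 60.0,
    rng_seed: int = 0,
    nof_scale: float = 30.0,
    max_redraws: int = 20,
) -> StructuralConnectome:
    """Distance-dependent intra-hemispheric connectome with NOF weights.

    Per hemisphere, ``round(density * n_pairs)`` undirected edges are
    drawn without replacement with probability proportional to
    exp(-d/decay_length); an edge's NOF weight is
    max(1, round(nof_scale * exp(-d/decay_length))), so shorter fibers
    are both more likely and stronger.  If a draw leaves the hemisphere
    disconnected it is redrawn (up to ``max_redraws`` times) and finally
    bridged by adding minimum-distance unit-weight edges between
    components.  Fails if the edge budget cannot connect the hemisphere
    at all (fewer edges than n-1).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    rng = np.random.default_rng(rng_seed)
    n = rois.n_rois
    w = np.zeros((n, n))
    coords = rois.centroids
    for hemi in ("L", "R"):
        idx = np.flatnonzero(rois.hemispheres == hemi)
        nh = len(idx)
        if nh < 2:
            continue
        d = squareform(pdist(coords[idx]))
        iu, ju = np.triu_indices(nh, k=1)
        pair_d = d[iu, ju]
        n_pairs = len(pair_d)
        m = int(round(density * n_pairs))
        if m < nh - 1:
            raise ValueError(
                f"density {density} gives {m} edges for {nh} ROIs in hemisphere "
                f"{hemi}; cannot form a connected graph (needs >= {nh - 1})"
            )
        kernel = np.exp(-pair_d / decay_length)
        probs = kernel / kernel.sum()
        for attempt in range(max_redraws + 1):
            chosen = rng.choice(n_pairs, size=m, replace=False, p=probs)
            sub = np.zeros((nh, nh))
            nof = np.maximum(1, np.round(nof_scale * kernel[chosen])).astype(float)
            sub[iu[chosen], ju[chosen]] = nof
            sub += sub.T
            n_comp, labels = connected_components(sub > 0, directed=False)
            if n_comp == 1:
                break
        while n_comp > 1:
            # bridge the two closest components with a unit-weight edge
            best = None
            for a in range(nh):
                for b in range(a + 1, nh):
                    if labels[a] != labels[b] and sub[a, b] == 0:
                        if best is None or d[a, b] < best[0]:
                            best = (d[a, b], a, b)
            _, a, b = best
            sub[a, b] = sub[b, a] = 1.0
            n_comp, labels = connected_components(sub > 0, directed=False)
        w[np.ix_(idx, idx)] = sub
    return StructuralConnectome(w, rois.roi_ids)


def _ridge_to_pd(sigma: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, float]:
    """Add the smallest power-of-10 ridge making min eigenvalue > min_eig."""
    eig = float(np.linalg.eigvalsh(sigma).min())
    if eig > min_eig:
        return sigma, 0.0
    ridge = 1e-10
    n = sigma.shape[0]
    while ridge <= 1e3:
        cand = sigma + ridge * np.eye(n)
        if float(np.linalg.eigvalsh(cand).min()) > min_eig:
            return cand, ridge
        ridge *= 10.0
    raise ValueError("covariance could not be made positive definite by ridging")


def generate_covariance(
    rois: RoiTable,
    connectome: StructuralConnectome | None = None,
    spatial_scale: float = 30.0,
    structural_gain: float = 0.6,
    hubs: Sequence[int] = (),
    hub_strength: float = 0.5,
    hub_range: float | None = None,
    noise_floor: float = 1.0,
) -> CovarianceModel:
    """Ground-truth activity covariance with unit marginal variances.

    The raw matrix is the sum of

    - a squared-exponential spatial kernel exp(-d^2 / (2 * spatial_scale^2))
      over all ROI pairs,
    - a connectome-mediated kernel ``structural_gain`` *
      exp(-d_con / structural_scale), where d_con is the shortest-path
      distance on the 1/NOF dissimilarity graph and ``structural_scale``
      defaults to the median finite intra-hemispheric d_con — so
      functional coupling decays with connectome proximity even between
      spatially distant regions,
    - ``hub_strength`` on pairs (hub, j) in the same hemisphere separated
      by more than ``hub_range`` mm (default 2 x spatial_scale): planted
      long-range functional links,
    - ``noise_floor`` x identity (region-specific independent variance);

    then ridged to positive definiteness if needed (smallest power-of-10
    ridge, recorded in ``params``) and rescaled to unit diagonal.
    """
    if spatial_scale <= 0:
        raise ValueError("spatial_scale must be positive")
    if noise_floor <= 0:
        raise ValueError("noise_floor must be positive")
    if hub_range is None:
        hub_range = 2.0 * spatial_scale
    d = squareform(pdist(rois.centroids))
    sigma = np.exp(-(d ** 2) / (2.0 * spatial_scale ** 2))
    structural_scale = np.nan
    if connectome is not None and structural_gain != 0.0 and connectome.weights.max() > 0:
        from .graphs import connectome_distances

        d_con = connectome_distances(connectome).d
        off = d_con[np.isfinite(d_con) & (d_con > 0)]
        structural_scale = float(np.median(off))
        with np.errstate(over="ignore"):
            kern = np.where(
                np.isfinite(d_con), np.exp(-d_con / structural_scale), 0.0
            )
        np.fill_diagonal(kern, 0.0)
        sigma = sigma + structural_gain * kern
    hemi = rois.hemispheres
    pos = {rid: i for i, rid in enumerate(rois.roi_ids)}
    for hub in hubs:
        i = pos[hub]
        far = (d[i] > hub_range) & (hemi == hemi[i])
        sigma[i, far] += hub_strength
        sigma[far, i] += hub_strength
    sigma = sigma + noise_floor * np.eye(rois.n_rois)
    sigma = 0.5 * (sigma + sigma.T)
    sigma, ridge = _ridge_to_pd(sigma)
    scale = 1.0 / np.sqrt(np.diag(sigma))
    sigma = sigma * np.outer(scale, scale)
    np.fill_diagonal(sigma, 1.0)
    return CovarianceModel(
        sigma,
        rois.roi_ids,
        params={
            "spatial_scale_mm": spatial_scale,
            "structural_gain": structural_gain,
            "structural_scale": structural_scale,
            "hubs": tuple(int(h) for h in hubs),
            "hub_strength": hub_strength,
            "hub_range_mm": hub_range,
            "noise_floor": noise_floor,
            "ridge": ridge,
        },
    )


def sample_subjects(
    model: CovarianceModel,
    n_subjects: int = 37,
    n_samples: int = 280,
    rng_seed: int = 0,
) -> list[ActivityMatrix]:
    """Draw per-subject ROI x sample matrices, i.i.d. zero-mean Gaussian.

    Defaults emulate the study conditions: 37 subjects with a 280-sample
    series per ROI.
    """
    if n_subjects < 1 or n_samples < 1:
        raise ValueError("n_subjects and n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    chol = np.linalg.cholesky(model.sigma)
    p = model.sigma.shape[0]
    out = []
    for _ in range(n_subjects):
        z = rng.standard_normal((p, n_samples))
        out.append(ActivityMatrix(chol @ z, model.roi_ids))
    return out


def structural_hubs(
    connectome: StructuralConnectome, rois: RoiTable, n_per_hemisphere: int = 2
) -> list[int]:
    """The top-strength (summed NOF) ROIs per hemisphere.

    A realistic choice of hub ROIs for :func:`generate_covariance`:
    cortical hubs with long-range functional links are also the most
    strongly structurally embedded regions (the "rich club"), so planting
    functional hubs at the structurally central nodes keeps the synthetic
    structure-function relationship coherent.
    """
    strength = connectome.weights.sum(axis=0)
    hubs: list[int] = []
    for h in ("L", "R"):
        ids = rois.hemisphere_ids(h)
        idx = rois.index_of(ids)
        order = np.argsort(-strength[idx], kind="stable")
        hubs.extend(int(ids[j]) for j in order[:n_per_hemisphere])
    return hubs


def _logdet(mat: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(mat)
    if sign <= 0:
        raise ValueError("singular covariance sub-block")
    return float(val)


def analytic_measure(
    model: CovarianceModel,
    measure: str,
    set_a: Iterable[int],
    set_b: Iterable[int] | None = None,
) -> float:
    """Exact Gaussian MI or TC (bits) from sub-blocks of the true covariance.

    ``measure='mi'`` needs two disjoint non-empty ROI sets and returns
    (1/2) log2( det S_A det S_B / det S_AB ); ``measure='tc'`` needs one
    set of >= 2 ROIs and returns -(1/2) log2 det(correlation sub-block)
    (marginal variances are 1 by construction).
    """
    a = list(set_a)
    if measure == "mi":
        if set_b is None:
            raise ValueError("mi requires two ROI sets")
        b = list(set_b)
        if not a or not b:
            raise ValueError("ROI sets must be non-empty")
        if set(a) & set(b):
            raise ValueError("ROI sets must be disjoint")
        la = _logdet(model.submatrix(a))
        lb = _logdet(model.submatrix(b))
        lab = _logdet(model.submatrix([*a, *b]))
        return 0.5 * (la + lb - lab) / _LN2
    if measure == "tc":
        if len(a) < 2:
            raise ValueError("tc requires at least 2 ROIs")
        return -0.5 * _logdet(model.submatrix(a)) / _LN2
    raise ValueError(f"unknown measure {measure!r}")
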