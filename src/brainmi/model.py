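"""Top-level modelling interface.

`PredictabilityModel` binds a pooled activity matrix, the ROI table, and
the structural connectome; `fit()` runs the multi-scale analysis —
neighbor rankings under the three metrics, scaling curves of the seed
and subsystem measures, per-ROI Total MI and Coupling Range — and
returns a `PredictabilityResults` object carrying the estimates with a
`summary()` table.  Follow-up analyses (structure-function correlation,
binned MI map, subsystem communities) hang off the results object so
expensive intermediates (entropy caches, rankings) are reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import communities as _communities
from . import graphs, maps, measures
from .data import ActivityMatrix, RoiTable, StructuralConnectome
from .entropy import EntropyCalculator, Estimator

__all__ = ["PredictabilityModel", "PredictabilityResults"]


class PredictabilityModel:
    """Multi-scale information-theoretic model of regional activity.

    Parameters
    ----------
    activity : ActivityMatrix
        Pooled (standardized, concatenated) ROI x sample matrix.
    rois : RoiTable
        ROI identities, hemispheres, centroids, anatomical areas.
    connectome : StructuralConnectome, optional
        Pooled NOF matrix; required for the connectome and randomized
        metrics.
    estimator : {'umvu', 'plugin'}
        Gaussian entropy estimator used throughout.
    """

    def __init__(
        self,
        activity: ActivityMatrix,
        rois: RoiTable,
        connectome: StructuralConnectome | None = None,
        estimator: Estimator = "umvu",
    ) -> None:
        if len(activity.roi_ids) != rois.n_rois or (
            activity.roi_ids != rois.roi_ids
        ).any():
            raise ValueError("activity roi_ids must match the ROI table order")
        if connectome is not None:
            if (connectome.roi_ids != rois.roi_ids).any():
                raise ValueError("connectome roi_ids must match the ROI table order")
            connectome.validate_hemispheres(rois)
        self.activity = activity
        self.rois = rois
        self.connectome = connectome
        self.estimator: Estimator = estimator

    @classmethod
    def from_files(
        cls,
        roi_path,
        activity_path,
        connectome_path=None,
        estimator: Estimator = "umvu",
    ) -> "PredictabilityModel":
        from .data import read_activity, read_connectome, read_roi_table

        rois = read_roi_table(roi_path)
        activity = read_activity(activity_path)
        connectome = read_connectome(connectome_path) if connectome_path else None
        return cls(activity, rois, connectome, estimator)

    def distance_matrices(
        self, rewire_seed: int = 0, swap_multiple: int = 10
    ) -> dict[str, graphs.DistanceMatrix]:
        """Euclidean, connectome, and randomized distance matrices."""
        out = {"euclidean": graphs.euclidean_distances(self.rois)}
        if self.connectome is not None:
            out["connectome"] = graphs.connectome_distances(self.connectome)
            rewired = graphs.rewire_connectome(
                self.connectome, self.rois, swap_multiple, rewire_seed
            )
            out["randomized"] = graphs.connectome_distances(rewired, "randomized")
        return out

    def fit(
        self,
        k_grid: Sequence[int] | None = None,
        metrics: Sequence[str] | None = None,
        measure_names: Sequence[str] = (
            "seed_neighbor_mi",
            "seed_subsystem_mi",
            "seed_environment_mi",
            "subsystem_integration_per_roi",
            "subsystem_environment_mi_per_roi",
        ),
        threshold_bits: float = 0.3,
        rewire_seed: int = 0,
        swap_multiple: int = 10,
    ) -> "PredictabilityResults":
        """Run the scaling analysis and return a results object.

        ``k_grid`` defaults to 1..min(hemisphere size - 1, n_samples/2)
        so the umvu estimator stays well-conditioned at the largest sets.
        """
        dists = self.distance_matrices(rewire_seed, swap_multiple)
        if metrics is None:
            metrics = tuple(dists)
        rankings = {m: graphs.rank_neighbors(dists[m], self.rois) for m in metrics}
        hemi_sizes = [len(self.rois.hemisphere_ids(h)) for h in ("L", "R")]
        min_hemi = min(s for s in hemi_sizes if s > 0)
        if k_grid is None:
            k_max = min(min_hemi - 1, self.activity.n_samples // 2)
            k_grid = range(1, k_max + 1)
        k_grid = [int(k) for k in k_grid]
        calc = EntropyCalculator(self.activity, estimator=self.estimator)
        seeds = [int(s) for h in ("L", "R") for s in self.rois.hemisphere_ids(h)]
        curves: dict[tuple[str, str], measures.ScalingCurve] = {}
        for metric in metrics:
            for name in measure_names:
                grid = [k for k in k_grid if self._valid_k(name, k, min_hemi)]
                curves[(name, metric)] = measures.scan_curves(
                    name, metric, grid, seeds, rankings[metric], calc, self.estimator
                )
        # Total MI is metric-independent
        total = pd.Series(
            {
                seed: measures.total_mi(
                    seed,
                    self.rois.hemisphere_ids(
                        self.rois.table.set_index("roi_id").loc[seed, "hemisphere"]
                    ),
                    calc,
                    self.estimator,
                )
                for seed in seeds
            },
            name="total_mi",
        )
        cr = None
        if "euclidean" in rankings:
            cr = measures.coupling_range_per_seed(
                seeds, rankings["euclidean"], calc, threshold_bits, self.estimator
            ).set_index("seed")
        return PredictabilityResults(
            model=self,
            k_grid=k_grid,
            curves=curves,
            total_mi=total,
            coupling_range=cr,
            rankings=rankings,
            distances=dists,
            calculator=calc,
            threshold_bits=threshold_bits,
        )

    @staticmethod
    def _valid_k(measure: str, k: int, hemi_size: int) -> bool:
        if measure in ("seed_subsystem_mi", "subsystem_integration_per_roi"):
            return 2 <= k <= hemi_size
        if measure in ("seed_environment_mi", "subsystem_environment_mi_per_roi"):
            return 1 <= k <= hemi_size - 1
        return 1 <= k <= hemi_size - 1  # seed_neighbor_mi


@dataclass
class PredictabilityResults:
    """Fitted multi-scale predictability estimates.

    Attributes
    ----------
    curves : dict of (measure, metric) -> ScalingCurve
    total_mi : Series, per-seed Total MI (bits)
    coupling_range : DataFrame, per-seed Coupling Range under the
        Euclidean metric with censoring flags
    """

    model: PredictabilityModel
    k_grid: list[int]
    curves: dict[tuple[str, str], measures.ScalingCurve]
    total_mi: pd.Series
    coupling_range: pd.DataFrame | None
    rankings: dict[str, graphs.NeighborRanking]
    distances: dict[str, graphs.DistanceMatrix]
    calculator: EntropyCalculator = field(repr=False, default=None)
    threshold_bits: float = 0.3

    def curve(self, measure: str, metric: str) -> measures.ScalingCurve:
        return self.curves[(measure, metric)]

    def curve_table(self) -> pd.DataFrame:
        """All per-seed curve values as one tidy frame."""
        return pd.concat([c.values for c in self.curves.values()], ignore_index=True)

    def summary_table(self) -> pd.DataFrame:
        """Cross-seed mean/Q1/Q3 per (measure, metric, k)."""
        return pd.concat([c.summary for c in self.curves.values()], ignore_index=True)

    def efficiency_correlation(self, k_grid=None) -> pd.DataFrame:
        """Pearson r between Seed-Environment MI and long-range efficiency."""
        if "euclidean" not in self.rankings:
            raise ValueError("euclidean ranking required")
        if k_grid is None:
            k_grid = [k for k in self.k_grid if k < min(
                len(self.model.rois.hemisphere_ids(h)) for h in ("L", "R")
            )]
        return maps.efficiency_mi_correlation(
            k_grid,
            self.model.rois,
            self.model.activity,
            self.rankings["euclidean"],
            self.distances,
            self.model.estimator,
        )

    def binned_mi_map(self, n_bins: int = 50) -> maps.BinnedMiMap:
        mi = maps.pairwise_mi_matrix(
            self.model.activity, self.model.rois, self.model.estimator
        )
        return maps.binned_mi_map(
            mi, self.distances["euclidean"], self.distances["connectome"], n_bins
        )

    def subsystem_communities(
        self,
        k: int = 11,
        metric: str = "connectome",
        percentile: float = 50.0,
        rng_seed: int = 0,
    ) -> pd.DataFrame:
        """Select jointly integrated + environment-coupled subsystems of
        size ``k``, cluster their overlap matrix, and assign ROIs.

        Returns the ROI-level assignment frame with a ``hemisphere``
        column (community -1 = unassigned).
        """
        integ = self.curves[("subsystem_integration_per_roi", metric)]
        env = self.curves[("subsystem_environment_mi_per_roi", metric)]
        frames = []
        for h in ("L", "R"):
            hemi_ids = set(self.model.rois.hemisphere_ids(h).tolist())
            iv = integ.values.query("k == @k and seed in @hemi_ids").set_index("seed")["value"]
            ev = env.values.query("k == @k and seed in @hemi_ids").set_index("seed")["value"]
            selected = _communities.select_subsystems(iv, ev, percentile)
            if not selected:
                frames.append(
                    pd.DataFrame(
                        {"roi_id": sorted(hemi_ids), "community": -1, "n_subsystems": 0}
                    ).assign(hemisphere=h)
                )
                continue
            subs = [
                graphs.build_subsystem(self.rankings[metric], seed, k)
                for seed in selected
            ]
            overlap = _communities.overlap_matrix(subs)
            assign = _communities.detect_communities(overlap, rng_seed)
            frame = _communities.assign_rois(assign, subs, sorted(hemi_ids))
            frames.append(frame.assign(hemisphere=h))
        return pd.concat(frames, ignore_index=True)

    def plot_scaling(self, measure: str, ax=None):
        """Plot a measure's cross-seed mean curve per metric with
        interquartile bands (the standard presentation of these scaling
        analyses).  Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"euclidean": "tab:red", "connectome": "tab:blue",
                  "randomized": "0.5"}
        for metric in self.rankings:
            key = (measure, metric)
            if key not in self.curves:
                continue
            summ = self.curves[key].summary
            color = colors.get(metric)
            ax.plot(summ["k"], summ["mean"], label=metric, color=color)
            ax.fill_between(summ["k"], summ["q1"], summ["q3"], alpha=0.2,
                            color=color)
        ax.set_xlabel("subsystem size k")
        unit = "bits/ROI" if measure.endswith("per_roi") else "bits"
        ax.set_ylabel(f"{measure} ({unit})")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable summary of the fitted measures."""
        lines = [
            "Multi-scale regional predictability (Gaussian information measures)",
            "=" * 68,
            f"ROIs: {self.model.rois.n_rois}  "
            f"samples: {self.model.activity.n_samples}  "
            f"estimator: {self.model.estimator}",
            f"k grid: {self.k_grid[0]}..{self.k_grid[-1]}  "
            f"metrics: {', '.join(self.rankings)}",
            "",
            "Total MI (bits) across seeds:",
            f"  mean {self.total_mi.mean():.3f}   "
            f"Q1 {self.total_mi.quantile(0.25):.3f}   "
            f"median {self.total_mi.median():.3f}   "
            f"Q3 {self.total_mi.quantile(0.75):.3f}",
        ]
        if self.coupling_range is not None:
            cr = self.coupling_range["coupling_range"]
            cens = int(self.coupling_range["censored"].sum())
            lines += [
                f"Coupling Range (threshold {self.threshold_bits} bits):",
                f"  mean {cr.mean():.1f}   median {cr.median():.1f}   "
                f"censored seeds: {cens}",
            ]
        lines.append("")
        lines.append("Cross-seed mean curves (bits; bits/ROI for per-ROI measures):")
        summary = self.summary_table()
        ks = sorted(set(self.k_grid))
        show_k = sorted({k for k in (2, 5, 10, max(ks)) if k in ks})
        for (name, metric), _ in self.curves.items():
            sub = summary.query("measure == @name and metric == @metric")
            vals = "  ".join(
                f"k={k}: {sub.loc[sub['k'] == k, 'mean'].squeeze():.3f}"
                for k in show_k
                if (sub["k"] == k).any()
            )
            lines.append(f"  {name:34s} [{metric:10s}] {vals}")
        return "\n".join(lines)
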