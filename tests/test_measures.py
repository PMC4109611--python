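import numpy as np
import pytest

import brainmi as bm
from brainmi import graphs, measures
from brainmi.data import ActivityMatrix
from brainmi.entropy import SingularDataError


class TestIdentityChain:
    def test_env_k1_equals_total_equals_full_subsystem(
        self, small_world, small_rankings, small_calcs
    ):
        """Seed-Environment MI at k=1, Total MI, and Seed-Subsystem MI at
        k = hemisphere size are the same quantity by definition."""
        rois = small_world["rois"]
        for est in ("umvu", "plugin"):
            calc = small_calcs[est]
            for metric, ranking in small_rankings.items():
                for hemi in ("L", "R"):
                    ids = rois.hemisphere_ids(hemi)
                    for seed in map(int, ids):
                        env1 = measures.seed_environment_mi(seed, 1, ranking, calc, est)
                        tot = measures.total_mi(seed, ids, calc, est)
                        full = measures.seed_subsystem_mi(
                            seed, len(ids), ranking, calc, est
                        )
                        assert env1 == pytest.approx(tot, abs=1e-10)
                        assert full == pytest.approx(tot, abs=1e-10)

    def test_subsystem_k2_equals_first_neighbor(
        self, small_rankings, small_calcs
    ):
        ranking = small_rankings["euclidean"]
        calc = small_calcs["umvu"]
        for seed in ranking.order:
            assert measures.seed_subsystem_mi(seed, 2, ranking, calc) == pytest.approx(
                measures.seed_neighbor_mi(seed, 1, ranking, calc)
            )

    def test_total_mi_metric_independent(
        self, small_world, small_rankings, small_calcs
    ):
        rois = small_world["rois"]
        calc = small_calcs["umvu"]
        ids = rois.hemisphere_ids("L")
        seed = int(ids[0])
        k_full = len(ids)
        vals = {
            metric: measures.seed_subsystem_mi(seed, k_full, ranking, calc)
            for metric, ranking in small_rankings.items()
        }
        assert len({round(v, 12) for v in vals.values()}) == 1


class TestMonotonicity:
    def test_plugin_monotone_in_k_for_every_seed(
        self, small_world, small_rankings, small_calcs
    ):
        """Plug-in Seed-Subsystem MI is exactly non-decreasing and plug-in
        Seed-Environment MI exactly non-increasing in subsystem size."""
        rois = small_world["rois"]
        calc = small_calcs["plugin"]
        ranking = small_rankings["euclidean"]
        for hemi in ("L", "R"):
            ids = rois.hemisphere_ids(hemi)
            size = len(ids)
            for seed in map(int, ids):
                ss = [
                    measures.seed_subsystem_mi(seed, k, ranking, calc, "plugin")
                    for k in range(2, size + 1)
                ]
                assert all(b >= a - 1e-12 for a, b in zip(ss, ss[1:]))
                se = [
                    measures.seed_environment_mi(seed, k, ranking, calc, "plugin")
                    for k in range(1, size)
                ]
                assert all(b <= a + 1e-12 for a, b in zip(se, se[1:]))

    def test_umvu_deviation_bounded_by_correction_difference(
        self, small_world, small_rankings, small_calcs
    ):
        """umvu deviations from plug-in monotonicity cannot exceed the
        analytic (k, n)-dependent correction differences."""
        from brainmi.entropy import umvu_plugin_gap

        calc_u = small_calcs["umvu"]
        calc_p = small_calcs["plugin"]
        ranking = small_rankings["euclidean"]
        n = small_world["pooled"].n_samples
        seed = next(iter(ranking.order))
        size = len(ranking.order[seed]) + 1
        for k in range(2, size):
            u = measures.seed_subsystem_mi(seed, k, ranking, calc_u, "umvu")
            p = measures.seed_subsystem_mi(seed, k, ranking, calc_p, "plugin")
            # MI over sets of sizes (1, k-1, k): gap difference is exact
            expected = (
                umvu_plugin_gap(1, n) + umvu_plugin_gap(k - 1, n) - umvu_plugin_gap(k, n)
            )
            assert u - p == pytest.approx(expected, abs=1e-10)


class TestCouplingRange:
    def test_first_crossing(self):
        rng, censored = measures.coupling_range([0.8, 0.5, 0.31, 0.29, 0.1], 0.3)
        assert (rng, censored) == (4, False)

    def test_never_crossing_is_censored_at_max_k(self):
        rng, censored = measures.coupling_range([0.8, 0.5, 0.4], 0.3)
        assert (rng, censored) == (3, True)

    def test_zero_threshold_censored(self):
        rng, censored = measures.coupling_range([0.5, 0.2, 0.05], 0.0)
        assert (rng, censored) == (3, True)

    def test_below_at_first_k(self):
        rng, censored = measures.coupling_range([0.1, 0.05], 0.3)
        assert (rng, censored) == (1, False)

    def test_empty_curve_fails(self):
        with pytest.raises(ValueError):
            measures.coupling_range([], 0.3)


class TestSubsystemMeasures:
    def test_integration_k2_is_half_pair_mi(self, small_rankings, small_calcs):
        ranking = small_rankings["euclidean"]
        calc = small_calcs["umvu"]
        for seed in ranking.order:
            integ = measures.subsystem_integration_per_roi(seed, 2, ranking, calc)
            pair_mi = measures.seed_neighbor_mi(seed, 1, ranking, calc)
            assert integ == pytest.approx(pair_mi / 2)

    def test_env_mi_k1_is_total_mi(self, small_world, small_rankings, small_calcs):
        rois = small_world["rois"]
        ranking = small_rankings["euclidean"]
        calc = small_calcs["umvu"]
        seed = int(rois.hemisphere_ids("L")[0])
        val = measures.subsystem_environment_mi_per_roi(seed, 1, ranking, calc)
        tot = measures.total_mi(seed, rois.hemisphere_ids("L"), calc)
        assert val == pytest.approx(tot)

    def test_independent_data_near_zero(self):
        from tests.conftest import make_roi_table

        rois = make_roi_table(
            [(10 * i, 0, 0) for i in range(1, 6)], ["L"] * 5
        )
        x = ActivityMatrix(
            np.random.default_rng(1).standard_normal((5, 20000)), rois.roi_ids
        )
        ranking = graphs.rank_neighbors(graphs.euclidean_distances(rois), rois)
        assert abs(measures.subsystem_integration_per_roi(0, 3, ranking, x)) < 0.01
        assert abs(measures.subsystem_environment_mi_per_roi(0, 3, ranking, x)) < 0.01

    def test_duplicated_series_raises_singularity(self, small_rankings):
        ranking = small_rankings["euclidean"]
        seed = next(iter(ranking.order))
        nb = ranking.neighbor(seed, 1)
        ids = np.array(sorted(ranking.order))
        vals = np.random.default_rng(2).standard_normal((len(ids), 100))
        pos = {r: i for i, r in enumerate(ids)}
        vals[pos[nb]] = vals[pos[seed]]  # perfectly dependent pair
        x = ActivityMatrix(vals, ids)
        with pytest.raises(SingularDataError):
            measures.seed_neighbor_mi(seed, 1, ranking, x)


class TestScanCurves:
    def test_single_seed_single_k(self, small_rankings, small_calcs):
        ranking = small_rankings["euclidean"]
        seed = next(iter(ranking.order))
        curve = measures.scan_curves(
            "seed_subsystem_mi", "euclidean", [2], [seed], ranking, small_calcs["umvu"]
        )
        assert len(curve.values) == 1
        assert curve.summary["mean"].iloc[0] == curve.values["value"].iloc[0]

    def test_quartile_ordering(self, small_world, small_rankings, small_calcs):
        rois = small_world["rois"]
        seeds = [int(s) for s in rois.hemisphere_ids("L")]
        curve = measures.scan_curves(
            "seed_environment_mi",
            "euclidean",
            [1, 2, 3],
            seeds,
            small_rankings["euclidean"],
            small_calcs["umvu"],
        )
        med = curve.values.groupby("k")["value"].median()
        for _, row in curve.summary.iterrows():
            assert row["q1"] <= med[row["k"]] + 1e-12
            assert med[row["k"]] <= row["q3"] + 1e-12

    def test_deterministic(self, small_rankings, small_calcs):
        ranking = small_rankings["euclidean"]
        seeds = list(ranking.order)[:3]
        kwargs = dict(
            measure="seed_subsystem_mi",
            metric="euclidean",
            k_grid=[2, 4],
            seeds=seeds,
            ranking=ranking,
            x=small_calcs["umvu"],
        )
        a = measures.scan_curves(**kwargs)
        b = measures.scan_curves(**kwargs)
        assert a.values.equals(b.values)

    def test_bad_grid_rejected(self, small_rankings, small_calcs):
        ranking = small_rankings["euclidean"]
        with pytest.raises(ValueError):
            measures.scan_curves(
                "seed_subsystem_mi", "euclidean", [3, 2],
                list(ranking.order)[:1], ranking, small_calcs["umvu"],
            )

    def test_failure_names_seed_and_k(self, small_rankings, small_calcs):
        ranking = small_rankings["euclidean"]
        seed = next(iter(ranking.order))
        with pytest.raises(RuntimeError, match=str(seed)):
            measures.scan_curves(
                "seed_subsystem_mi", "euclidean", [1], [seed], ranking,
                small_calcs["umvu"],
            )


class TestSpatialDecayPattern:
    def test_neighbor_mi_decreases_with_euclidean_rank(self):
        """On spatially decaying ground truth, mean analytic Seed-Neighbor
        MI falls with Euclidean neighbor rank."""
        rois = bm.generate_roi_geometry(12, extent=100, rng_seed=30)
        cov = bm.generate_covariance(rois, None, spatial_scale=30.0)
        ranking = graphs.rank_neighbors(graphs.euclidean_distances(rois), rois)
        seeds = [int(s) for s in rois.roi_ids]
        means = [
            np.mean(
                [
                    bm.analytic_measure(
                        cov, "mi", [s], [ranking.neighbor(s, k)]
                    )
                    for s in seeds
                ]
            )
            for k in (1, 5, 10)
        ]
        assert means[0] > means[1] > means[2]
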