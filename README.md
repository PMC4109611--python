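# brainmi

Multi-scale information-theoretic analysis of regional brain activity.

## The problem

Resting-state activity in the cortex is strongly coupled between nearby
regions and more weakly — but systematically — coupled over long range,
where the white-matter connectome mediates the interaction.  This package
quantifies that organization with information theory.  Given a
parcellation of each hemisphere into regions of interest (ROIs), their
centroid coordinates, an ROI × time activity matrix, and a structural
connectome weighted by number of fibers (NOF), it measures how
predictable each region's activity is from region sets defined at every
spatial scale, and how internally integrated versus externally coupled
those sets are.

Region sets are built from neighbor rankings under three distance
metrics:

- **Euclidean** — distance between ROI centroids (mm);
- **Connectome** — shortest-path distance on the graph with edge lengths
  1/NOF;
- **Randomized** — the same construction on a degree-preserving
  (Maslov–Sneppen) rewiring of the connectome, a null model.

For a seed ROI *i*, its *k*th-ranked neighbor is *n_i(k)*, the size-*k*
subsystem *S_i(k)* is the seed plus its *k* − 1 nearest neighbors, and the
environment *E_i(k)* is the rest of the hemisphere.

## The measures

All quantities are computed in bits under a multivariate Gaussian
assumption, with differential entropies estimated by the uniformly
minimum-variance unbiased (UMVU) estimator

H&#770;(X) = (1/ln 2) [ (k/2) ln(eπ) + ½ ln|XX′| − ½ Σᵢ ψ((n + 1 − i)/2) ]

for a k × n zero-mean data matrix X (ψ is the digamma function); a
plug-in estimator is available for its exact monotonicity properties.
From H the package derives MI, I(X;Y) = H(X) + H(Y) − H(X,Y), and total
correlation, TC(X₁,…,X_k) = Σ H(Xᵢ) − H(X₁,…,X_k), and computes:

| measure | definition | meaning |
| --- | --- | --- |
| Seed-Neighbor MI | I(i; n_i(k)) | pairwise coupling at rank k |
| Seed-Subsystem MI | I(i; S_i(k)\i) | how well the local set predicts the seed |
| Total MI | I(i; V\i) | all prediction available about the seed |
| Seed-Environment MI | I(i; E_i(k)) | coupling to everything outside the subsystem |
| Coupling Range | first k with I(i; E_i(k)) < θ | spatial reach of coupling (θ = 0.3 bits) |
| Subsystem Integration | TC(S_i(k))/k | internal integration per ROI |
| Subsystem-Environment MI | I(S_i(k); E_i(k))/k | segregation from the rest per ROI |

Follow-up analyses: pairwise-MI maps binned on Euclidean × connectome
distance; the Pearson correlation across seeds between Seed-Environment
MI and long-range efficiency (mean inverse shortest-path distance to the
Euclidean environment) under each metric; and "subsystem communities" —
Louvain clusters of the overlap matrix of subsystems that are jointly
high in integration and environment coupling.

Because no subject recordings are distributed, `brainmi.simulate`
generates synthetic data with the same statistical structure (two
mirrored hemispheres, a distance-dependent NOF connectome,
spatially decaying plus connectome-mediated Gaussian covariance, planted
functional hubs) together with an analytic oracle for every measure.

## Worked example

```python
import brainmi as bm
from brainmi.study import make_synthetic_study

study = make_synthetic_study(7)          # 20 ROIs/hemisphere, n = 5,000
model = bm.PredictabilityModel(study.pooled, study.rois, study.connectome)
res = model.fit(k_grid=range(1, 11), rewire_seed=7)
print(res.summary())
```

prints (excerpt):

```
Multi-scale regional predictability (Gaussian information measures)
====================================================================
ROIs: 40  samples: 5000  estimator: umvu
k grid: 1..10  metrics: euclidean, connectome, randomized

Total MI (bits) across seeds:
  mean 0.201   Q1 0.143   median 0.182   Q3 0.229
Coupling Range (threshold 0.3 bits):
  mean 1.4   median 1.0   censored seeds: 0

Cross-seed mean curves (bits; bits/ROI for per-ROI measures):
  seed_subsystem_mi                  [euclidean ] k=2: 0.096  k=5: 0.154  k=10: 0.171
  seed_subsystem_mi                  [connectome] k=2: 0.090  k=5: 0.133  k=10: 0.166
  seed_subsystem_mi                  [randomized] k=2: 0.024  k=5: 0.083  k=10: 0.131
  subsystem_environment_mi_per_roi   [euclidean ] k=2: 0.133  k=5: 0.107  k=10: 0.062
  subsystem_environment_mi_per_roi   [connectome] k=2: 0.156  k=5: 0.135  k=10: 0.079
  subsystem_environment_mi_per_roi   [randomized] k=2: 0.190  k=5: 0.161  k=10: 0.092
```

The orderings carry the scientific content: subsystems assembled from
Euclidean or connectome neighbors predict their seed far better than
rewired-null subsystems (0.154 and 0.133 vs 0.083 bits at k = 5), while
randomized subsystems are the least segregated from their environment
(0.161 vs 0.107 bits/ROI).  Structure-function coupling follows from

```python
tab = res.efficiency_correlation([6, 8, 10, 12, 14])
print(tab.pivot(index="k", columns="metric", values="r_mean").round(3))
```

```
metric  connectome  euclidean  randomized
k
6            0.557      0.390       0.359
8            0.535      0.328       0.396
10           0.540      0.355       0.419
```

— seeds whose distant environments predict them best are the seeds most
efficiently reachable over the true connectome, an alignment the rewired
null largely destroys.

A `brainmi` command-line tool exposes the same pipeline over
tab-delimited text files (`simulate`, `preprocess`, `rank`, `scale`,
`range`, `sfcorr`, `communities`); every seed-bearing step requires an
explicit `--seed` and writes a provenance manifest.

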