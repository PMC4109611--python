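# Methods

## Model and assumptions

All measures treat the pooled ROI × sample activity matrix as n i.i.d.
draws from a zero-mean multivariate Gaussian.  Under that assumption the
sample covariance is a sufficient statistic for every quantity the
package computes, and each measure is a combination of joint
differential entropies of ROI subsets.  Mutual information
I(X;Y) = H(X) + H(Y) − H(X,Y) and total correlation
TC = Σ H(Xᵢ) − H(X₁,…,X_k) are coordinate-free (invariant to per-ROI
affine maps) and nonnegative for the true distribution; the plug-in
estimates inherit both properties exactly, the UMVU estimates up to an
analytic correction term (below).

Stationarity and Gaussianity are assumptions, not checks: temporal
autocorrelation in real recordings reduces the effective sample size,
and non-Gaussian dependence is invisible to these estimators.  Both
hemispheres are analyzed separately (inter-hemispheric structural
connections are not trusted), and all neighbor sets are restricted to
the seed's hemisphere.

## Entropy estimation

For a k × n data matrix X the UMVU estimator of Gaussian differential
entropy in bits is

    (1/ln 2) [ (k/2) ln(eπ) + ½ ln|XX′| − ½ Σ_{i=1..k} ψ((n+1−i)/2) ].

The digamma arguments (n+1−i)/2 correspond to an n-degree-of-freedom
Wishart Gram matrix, i.e. to data whose mean is known to be zero.  The
estimator is therefore applied to the data as given, with no internal
re-centering: the preprocessing pipeline standardizes every ROI series
to mean 0 and SD 1 before pooling, so the zero-mean premise holds by
construction, and on genuinely zero-mean input the estimator is exactly
unbiased.  A `center=True` option removes row means first; this restores
shift invariance for arbitrary (un-standardized) input at the cost of an
O(1/n) bias, because centered data have an (n−1)-df Gram matrix while
the digamma corrections still assume n.  The affine-invariance property
tests therefore run with centering enabled; the bias calibration runs on
zero-mean draws without it.

The plug-in estimator uses (k/2) log₂(2πe) + ½ log₂ det(XX′/n).  The
difference umvu − plugin is a closed-form function of (k, n) only —
`umvu_plugin_gap` — which yields two useful exact facts: plug-in MI/TC
are nonnegative and exactly monotone under set inclusion (log-determinant
inequalities on a Gram matrix), and any UMVU deviation from those
monotonicities is bounded by differences of the analytic gap.

Numerics: all log-determinants go through Cholesky factorization of the
relevant Gram/covariance sub-block, never a raw determinant, so sets of
a few hundred ROIs are safe.  A relative Cholesky pivot at or below
1e−6 of the largest pivot is treated as rank deficiency and raised as a
singularity error naming the offending ROI set (duplicated or constant
series).  An `EntropyCalculator` precomputes the full Gram matrix once
and caches joint entropies keyed by frozen ROI set, because environment
entropies recur heavily when scanning subsystem sizes across seeds.

## Preprocessing

Per subject: the first 4 samples are dropped (signal stabilization);
subjects whose maximum across-ROI variance over time points exceeds
Q3 + 1.5·IQR (Tukey's rule, quartiles by linear interpolation — the
convention is recorded in the output manifest because the threshold
depends on it) are rejected; each ROI series is mean-centered and scaled
to SD 1; subjects are concatenated sample-wise.  Structural connectomes
are pooled by element-wise averaging.  A zero-variance ROI series is an
error rather than a silent drop, since removing a row would desynchronize
the activity matrix from the ROI table and connectome.

## Distance metrics and graph operations

Euclidean distances come from ROI centroids.  The connectome metric is
the all-pairs shortest path (Dijkstra) on the dissimilarity graph with
edge length 1/NOF; absent fibers mean absent edges, and unreachable
pairs get distance +∞ (ranked last, contributing 0 to efficiency — this
keeps the hemisphere ROI set intact for the subsystem/environment
algebra).  The randomized metric repeats the construction on a
Maslov–Sneppen rewiring: repeated double-edge swaps in which edges carry
their NOF weights, rejecting self-loops and multi-edges, preserving the
degree sequence, edge count, and weight multiset exactly; the default
budget is 10 × (edge count) attempted swaps per hemisphere, applied to
each hemisphere independently so the inter-hemispheric block stays zero.
Neighbor rankings break distance ties by ascending roi_id so every
downstream result is reproducible.

Coupling Range reports the first k (no interpolation, matching the
discrete neighbor-number definition) at which Seed-Environment MI drops
below the threshold, default 0.3 bits; a curve that never crosses is
reported censored at the largest k rather than NaN so per-ROI maps stay
totally ordered.

## Subsystem communities

At a fixed subsystem size (default k = 11 for real-scale data; smaller
in the reduced test conditions) the connectome subsystems strictly above
the hemisphere median on both Subsystem Integration and
Subsystem-Environment MI are selected (strictly-above rather than ≥, so
an all-constant measure selects nothing).  Their pairwise overlap matrix
(|A ∩ B| / k, diagonal zeroed so self-overlap cannot inflate modularity)
is clustered by Louvain modularity maximization at resolution 1.0 with a
settable seed; community ids are ordered by decreasing size.  Each ROI
in at least one selected subsystem is assigned to its most frequent
community, ties to the lowest community id; all other ROIs are
explicitly unassigned.

## Synthetic data generator

The generator stands in for non-distributed subject recordings; its
defaults define the study conditions used by the validation suite.

- **Geometry** — per hemisphere, centroids uniform in a 100 mm box,
  offset 5 mm from the mid-sagittal plane; the right hemisphere is the
  mirror image of the left, keeping the two per-hemisphere analyses
  statistically identical.  20 ROIs per hemisphere by default: large
  enough for distinct local/mid/long-range scales, small enough that
  the full k-scan and 20-run Monte Carlo finish in seconds.
- **Connectome** — per hemisphere, round(density · n_pairs) edges drawn
  without replacement with probability ∝ exp(−d/λ), NOF weight
  max(1, round(30 · exp(−d/λ))); density 0.3, λ = 60 mm.  The long decay
  keeps the connectome from collapsing onto pure spatial proximity, so
  the connectome metric is informative beyond the Euclidean one.
  Disconnected draws are redrawn and finally bridged with unit-weight
  minimum-distance edges; an edge budget below n−1 fails outright.
- **Covariance** — sum of a squared-exponential spatial kernel
  exp(−d²/2ℓ²) with ℓ = 30 mm, a connectome-mediated kernel
  g · exp(−d_con/s) with g = 0.6 and s the median finite intra-hemispheric
  connectome distance (so functional coupling decays with structural
  proximity, including multi-hop paths), hub couplings of 0.5 added
  between each hub and its same-hemisphere ROIs beyond 2ℓ, and a unit
  noise floor; then symmetrized, ridged to positive definiteness if
  needed (smallest power-of-10 ridge, recorded), and rescaled to unit
  diagonal.  Hubs default to the two highest-strength connectome nodes
  per hemisphere — cortical hubs with long-range functional links are
  also the most strongly structurally embedded regions, and placing them
  elsewhere would decouple the planted functional structure from the
  connectome that the structure-function analyses interrogate.
- **Sampling** — i.i.d. zero-mean Gaussian draws via Cholesky;
  5,000 pooled samples by default in the validation conditions (37 × 280
  with 4-sample trimming when emulating the subject-level bookkeeping).
  The covariance itself never consumes randomness; only sampling,
  geometry, connectome drawing, rewiring, and Louvain take seeds, each
  through its own seeded generator.

The generator reproduces the *statistical* structure the analyses
assume — spatial decay, connectome-mediated long-range coupling,
functional hubs, two mirrored hemispheres — and nothing physiological:
no hemodynamics, no temporal autocorrelation, no non-Gaussian tails, no
measurement noise structure.  Passing tests therefore demonstrate that
the estimators and pipeline recover planted structure under the model's
own assumptions, not that real recordings satisfy those assumptions.
The ground-truth covariance doubles as an analytic oracle
(`analytic_measure`), giving exact Gaussian MI/TC values from sub-block
log-determinants against which the sample-based estimators are checked.

## Validation conditions and problem sizes

The Monte Carlo validation runs 20 independent studies (fresh geometry,
connectome, hubs, and samples per master seed) at 20 ROIs/hemisphere and
n = 5,000 and checks: the metric ordering of mean Seed-Subsystem MI
(Euclidean ≥ Connectome > Randomized at k = 5) and mean
Subsystem-Environment MI per ROI (Randomized > Connectome ≥ Euclidean);
hub recovery (planted hubs in the top quartile of Coupling Range); and
the structure-function contrast (Seed-Environment-MI/efficiency Pearson
r averaged over the mid-range band k ∈ {6, 8, 10, 12, 14} larger under
the connectome metric than the rewired null).  "Mid-range" here means
subsystem sizes between the local coupling scale and the hemisphere
size, the regime where environments consist mostly of spatially distant
ROIs; at this system size a single k gives a noisy Pearson r over 20
seeds per hemisphere, so the band mean is used.  Exact-identity,
monotonicity, and graph-oracle checks run on a 12-ROI fixture with
n = 2,000.

## Known limitations

- The UMVU estimator's unbiasedness rests on the zero-mean premise;
  feeding raw, un-standardized data without `center=True` biases
  absolute entropies (MI/TC differences are far less sensitive).
- Pearson correlations over tens of seeds are noisy; the
  structure-function contrast is a population statement verified as a
  rate over repeated studies, not a per-dataset guarantee.
- Louvain is stochastic; community results are reproducible only via
  the recorded seed.  A consensus mode is not implemented.
- The rewiring null preserves the degree sequence, so degree-driven
  efficiency differences survive randomization by construction; the
  contrast isolates the contribution of *which* regions are connected,
  not *how many* connections each has.
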