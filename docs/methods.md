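# Methods

`dfcstates` implements a dynamic functional connectivity (dFC) state
analysis of resting-state ROI time series, and validates it end-to-end on
synthetic cohorts with planted ground truth.  This note records the model,
the parameter choices that matter, and the design decisions taken where
the procedure was genuinely open.

## Windowed connectivity

A subject is an L x M matrix of region signals sampled every TR seconds
(defaults mirror a typical protocol: TR = 2 s, M atlas regions).  A
rectangular window of w TRs is slid with step 1 TR (both configurable;
window length is specified in seconds and converted as
w = round(seconds / TR), so the 30 s default gives w = 15).  Inside each
window the Pearson correlation r_ij is computed for every region pair and
variance-stabilized with the Fisher R-Z transform z = arctanh(r).
Correlations with |r| >= 1 - 1e-7 are clamped before the transform so
outputs stay finite; the diagonal (self-correlation) is set to 0 and
excluded from every downstream vector and metric.  No taper is applied.
Windows shorter than 3 TRs, constant columns, and windows longer than the
series are rejected with explicit errors.

## Two-stage state clustering

The clustering feature is the vectorized upper triangle of a window's
Fisher-Z matrix (length M(M-1)/2).  Stage 1 reduces redundancy by
resampling: for each subject the `n_exemplars = 7` windows with the
largest FC-entry variance (population variance of the vector entries,
ties broken toward earlier windows) are pooled across all subjects and
groups and clustered with k-means (50 k-means++ restarts, best inertia
kept).  Stage 2 runs a single k-means to convergence on all windows of
all subjects, initialized at the stage-1 centroids.  States are ordered
by descending centroid mean and the window labels relabelled to match;
occupancy is the fraction of all windows per state.

Distances are L1 (Manhattan) by default — the customary choice for
high-dimensional FC vectors.  Under an L1 objective the cost-minimizing
cluster center is the coordinate-wise median, so the default update rule
is the median; this makes the recorded inertia (sum of L1 distances to
assigned centroids, logged after every assignment step) provably
non-increasing across iterations, a contract the test suite asserts on
every run.  A coordinate-wise mean update — the squared-error convention —
is available via `update="mean"`, but it does not carry the monotonicity
guarantee for the L1 objective (moving a center from the cluster median
toward the mean can raise L1 cost), which is why it is not the default.
Assignment ties go to the lowest centroid index; a cluster emptied by an
update is re-seeded at the sample farthest from its assigned centroid and
the event is recorded in the result.

### Choosing k

For each candidate k (default 2..10) the elbow statistic is
ratio(k) = (mean distance of samples to their own centroid) /
(mean pairwise distance between centroids).  The ratio falls while extra
clusters absorb genuinely separated structure and turns back up once a
true cluster is split, because the split halves pull two centroids close
together and shrink the denominator.  The chosen k is therefore the first
local minimum of the curve.  A curvature-based rule (maximum second
difference) was tried first and proved unreliable on realistic noise
levels — the curve is too shallow for curvature maxima to be stable — so
the local-minimum rule is used; the full curve is always returned so a
caller can override k manually (`--k`).

### Bootstrap stability

Stability is assessed by resampling subjects with replacement (the
natural exchangeable unit; windows within a subject are strongly
dependent), rerunning the full two-stage procedure per replicate, and
Hungarian-matching replicate centroids to the full-cohort centroids by
Pearson correlation.  The similarity table reports per-state matched
correlation and occupancy for each replicate.

## Temporal dynamics

From each subject's window-state sequence: occupancy per state, mean
dwelling time (mean length of maximal runs, in windows; multiply by
step * TR for seconds), visit counts, and the transition count (adjacent
unequal labels).  Mean dwell times of unvisited states are recorded as 0
with 0 visits and excluded (not zero-imputed) from dwell-time group
tests, since absence and short dwell are different things.  Group
differences use a pooled-variance two-sample t-test (Welch optional).
The identity sum_s(dwell_s * visits_s) = N holds for every subject and is
property-tested.

## Graph indicators

A state matrix is thresholded at tau = 0.3 in Fisher-Z units: entries
strictly below tau (negatives included) become 0.  Triangle- and
path-based indicators use the binary graph, matching their binary-graph
formulas: clustering coefficient CC_i = 2 t_i / (k_i (k_i - 1)),
characteristic path length (mean shortest path over reachable pairs only,
with the count of excluded unreachable pairs reported), global efficiency
(mean 1/d with 1/inf = 0, well defined on disconnected graphs), and local
efficiency (global efficiency of each node's neighbour-induced subgraph).
Weighted degree (row sum of surviving weights) is reported alongside
binary degree.  Modules come from Louvain modularity maximization (10
seeded restarts, best Q kept; the partition algorithm is a free choice —
any modularity maximizer would do).  Hub roles use the standard
participation coefficient P_i = 1 - sum_m (k_im / k_i)^2 and the
within-module degree z-score with a population-sd denominator (the
Guimera-Amaral convention).  Every binary indicator is checked exactly
against brute-force enumeration on hundreds of random graphs with <= 8
nodes.

## Edge statistics

A subject's edge value for a state is the element-wise mean of its
windowed Fisher-Z matrices assigned to that state; subjects with no
window in the state are excluded and logged.  Per-edge pooled-variance
t-tests feed two corrections: the network-based statistic (NBS) —
connected components of edges with |t| >= 3.0 (default primary threshold,
configurable; 5000 permutations by default), sized in edges, compared
against the max-component-size null from full relabelling of subjects —
and edge-wise Benjamini-Hochberg FDR.  Component p-values are
(1 + #{perm max >= size}) / (P + 1), so they are bounded below by
1/(P+1) and valid by construction.

## Synthetic cohorts

The generator emulates preprocessed ROI series with piecewise-stationary
covariance: a first-order Markov chain over K = 4 states selects, per
time point, a state correlation matrix; the observation is a zero-mean
multivariate normal draw plus isotropic noise (sd 0.2).  Defaults define
the reference study conditions used throughout the tests: three groups of
30 subjects, M = 30 regions, L = 150 time points at TR = 2 s.

- **States.**  Mean off-diagonal correlations descend 0.58 / 0.39 / 0.25 /
  0.20.  Each state is a block (modular) correlation matrix over 5
  modules; within-module correlations exceed between-module ones with a
  contrast of 0.8 (shrunk per state where needed to keep the matrix a
  valid correlation with the exact target mean), and the node-to-module
  assignment is independently permuted per state.  States are therefore
  distinct connectivity *patterns* with prescribed means — the structure
  recurring FC states show in practice, and the regime in which a
  window-level clustering is a meaningful estimator.  Failed
  positive-definiteness is repaired by adding eps*I (eps = 1e-6, doubled
  until SPD) with a log record.
- **Switching.**  Sticky chains T = s*I + (1-s) 1 pi^T with stationary
  occupancy pi = (0.16, 0.35, 0.38, 0.11) — the two middle states carry
  > 70% of the mass — and self-stay s = 0.995 / 0.9925 / 0.990 for the
  control-like and two patient-like groups, so the control group is the
  most stable.  Dwell is long relative to the 15-TR window: most windows
  are single-state, a minority of subjects switch once per scan.  Dwell
  times this long relative to the scan are the regime where window-major
  state labels are well defined; faster planted switching (self-stay
  0.95 vs 0.80) is used where the point is the transition-count contrast
  itself.
- **What it does not model.**  No hemodynamic response, no temporal
  autocorrelation within a state, no motion or drift, no spatial noise
  correlation.  Passing tests therefore demonstrate the estimator chain
  recovers piecewise-stationary Gaussian structure; they do not certify
  behaviour under HRF smoothing or artifacts, which real pipelines remove
  upstream.
- An edge-level Gaussian two-group simulator (`simulate_edge_groups`)
  generates unit-variance independent edges with an optional mean shift
  on a chosen edge set; it calibrates the NBS type-I error and power
  without the expense of full time-series simulation.

## Problem sizes and numerics

The validation suite runs the reference cohort (90 subjects, 12,240
windows of 435 edges), 20 elbow replicates, B = 20 bootstrap replicates,
a 30-60 s window sweep, 200 null and 50 effect replicates for NBS
calibration, and exhaustive k-means enumeration on 12-sample instances —
sizes chosen so the full suite completes in minutes on one core while
keeping every statistical check adequately powered.  All randomness
flows from per-stage seeds split from one master seed with
`numpy.random.SeedSequence`; identical configurations reproduce
bit-identical outputs.  Known limitations: the elbow rule assumes the
ratio curve is informative (heavily overlapping states defeat any k
selection); NBS power depends on the primary threshold, which the
analysis cannot choose automatically; and covariate adjustment of group
tests is out of scope.
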