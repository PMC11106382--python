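# Methods

This package implements a whole-brain functional-network analysis for
comparing a patient group (juvenile myoclonic epilepsy is the motivating
condition) against healthy controls, together with a synthetic cohort
generator that plants the group differences and hidden state dynamics the
analysis is designed to find.  The pipeline has six stages: static
functional connectivity (FC) networks, graph-theoretic topology metrics,
covariate-adjusted nodal group statistics, sliding-window Granger causality
on the abnormal regions, k-means state decomposition of the windowed
effective-connectivity (EC) matrices, and per-state causal-flow group
statistics.

## Static networks

Each subject contributes a T x N matrix of ROI time series (defaults
T = 190 volumes at TR = 2 s, N = 90 AAL cortical/subcortical parcels).  The
N x N Pearson correlation matrix is Fisher r-to-z transformed (a strictly
monotone map, so edge ranking is unchanged) and binarized at every sparsity
on a grid from 0.10 to 0.34 in steps of 0.01: at sparsity s the
round(s·N(N−1)/2) strongest off-diagonal entries become edges.

Ranking uses the signed value (most positive first); negative correlations
are therefore effectively never selected at the studied sparsities.  A
`rank_by="abs"` option ranks by magnitude instead.  Ties at the cut are
broken deterministically (larger value, then smaller row, then smaller
column index).

The analyzed sub-grid is restricted by two admissibility criteria applied
to every subject: mean degree above 2·log(N) and small-world sigma above
1.1.  The log is natural by default (configurable); under natural log the
bound for N = 90 is 8.997, which the 0.10 grid point (mean degree 8.911)
narrowly fails, so the admissible range typically starts at 0.11.

## Graph metrics

Global: mean clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc, and the small-world ratios
gamma = Cp/⟨Cp_null⟩, lambda = Lp/⟨Lp_null⟩, sigma = gamma/lambda.  Null
ensembles are degree-preserving double-edge-swap (Maslov–Sneppen) rewirings
— 100 nulls, 10 swap attempts per edge by default, seeded per (subject,
sparsity).  Nodal: degree, unnormalized betweenness (undirected pairs
counted once), and nodal efficiency (mean inverse distance to all other
nodes).

Thresholded graphs can be disconnected; we use the standard conventions:
Lp averages finite-distance pairs only, and efficiencies count an infinite
distance as zero contribution.  Shortest paths are computed by BFS
(scipy.sparse.csgraph), betweenness and rewiring by igraph; the test suite
checks all metrics against brute-force enumeration on small graphs.

Each metric is summarized per subject as the trapezoidal area under its
curve (AUC) across the admissible sparsity grid, giving one
threshold-independent scalar per subject (and per node, for nodal metrics).

## Group statistics

Group comparisons fit an ordinary least squares model
`value ~ group + age + sex` and report the group coefficient's t statistic
and two-sided p-value; constant covariates are dropped, in which case the
test reduces exactly to the pooled-variance two-sample t-test.  P-values
are corrected with Benjamini–Hochberg FDR *within each metric family* (one
family per metric at the AUC level); the study-level choice of FDR family
is not uniquely determined by the analysis description, and per-family
control is the conservative reproducible reading.  Nodes significant on any
nodal metric form the abnormal-node report, each labeled
increased/decreased by the sign of (patient mean − control mean); this
report is the default ROI hand-off to the dynamic stage.  Clinical
associations (NHS3 severity, epilepsy duration) use Spearman rank
correlation with average ranks for ties, FDR within each clinical variable.

## Sliding-window Granger causality

For the ROI subset, windows of 22 TR (44 s) advance 1 TR at a time —
190 volumes give 169 windows.  Within each window and for each ordered ROI
pair the joint autoregressive model

    y_t = Σ_k A_k x_{t−k} + Σ_k B_k y_{t−k} + C z_t + e_t

(and symmetrically for x) is estimated by OLS with an intercept; the signed
path coefficient Σ_k A_k (A_1 at the default order p = 1) is the directed
influence x→y.  One n x n EC matrix per window is assembled from these.
Design choices, each configurable: the model is *pairwise* (bivariate), not
conditioned on the remaining ROIs; p = 1, since a 22-sample window cannot
support a larger order; windows are rectangular with no detrending; window
covariates z_t default to the intercept only.  Rank-deficient windows are
flagged and their entries set to zero.

Direction calls compare the *standardized* path coefficients (|A|/se)
between the two directions: the raw magnitudes are not comparable because
the two equations generally have different residual variances — with a
planted x→y coupling of 0.6 and unit-variance x, the reverse equation's
residual is the full variance of x, inflating the reverse coefficient's
sampling noise an order of magnitude above the forward one.

## State decomposition

All subjects' windowed EC matrices are vectorized (off-diagonal entries,
row-major) and pooled, so both groups share one state space.  Clustering is
a hybrid k-means: assignment by Manhattan (L1) distance, centroid update by
the cluster mean, iterated to an assignment fixed point (cap 300
iterations), best of 50 restarts by within-cluster summed squared error
(the analysis drivers and acceptance checks use 10–20 restarts; on the
synthetic cohort the objective is insensitive to restarts beyond ~10).
The mean is not the L1-optimal center (the component-wise median is); the
hybrid follows the method description this package reproduces.  Empty
clusters are re-seeded at the point farthest from its centroid.  The number
of states is chosen by the silhouette coefficient under L1, with
Calinski–Harabasz as tie-breaker and smaller k as the final tie-break; for
pooled sets above 2000 windows the silhouette is evaluated on a seeded
2000-point subsample.  Occupancy is the fraction of windows per state,
overall and per group.  Per-state causal flow: each subject's mean EC
matrix over their windows in a state yields in-weighted (column sums) and
out-weighted (row sums) degree per node; subjects with no window in a state
are excluded listwise from that state's tests.  Total in- and out-flow are
equal by construction, which the tests assert.

## Synthetic cohort generator

The generator emulates preprocessed resting-state BOLD at the study's
dimensions: 20 patients + 20 controls, 190 TRs, 90 ROIs, signals band-
limited to 0.01–0.08 Hz at TR = 2 s.  It is a statistical stand-in, not a
biophysical model: no hemodynamic convolution, physiological noise, head
motion, or scanner drift.  Passing tests demonstrate that the pipeline
recovers planted structure under these idealized conditions; they say
nothing about robustness to the artifacts real preprocessing leaves behind.

**Background.**  Gaussian noise is given a modular N x N target correlation
(six contiguous 15-node modules on a ring: within-module r = 0.40,
adjacent-module 0.15, distant 0.03) via the symmetric matrix square root,
then band-pass filtered column-wise with a zero-phase FIR filter (no phase
distortion, so lagged structure is not biased).  This yields binarized
graphs that are small-world across the whole sparsity grid (sigma ≈ 1.4–3).

**Group effect.**  Patient correlation targets scale every edge incident to
a deficit node by (1 − effect_size) and to an enhanced node by
(1 + effect_size), default effect_size 0.5, then project to the nearest
valid correlation matrix (eigenvalue clipping + diagonal renormalization).
Planted nodes get atypical baselines so the effect moves their edges across
the sparsity cut rather than sliding with the bulk edge distribution:
deficit nodes (defaults DCG.L, PAL.L, STG.L) are within-module hubs
(r = 0.66); enhanced nodes (defaults SOG.R, SPG.R, ANG.R) hold
within-module edges at 0.34 and adjacent-module edges at 0.28, just below
the cuts that the 1.5x boost crosses.  With homogeneous baselines a node's marginal edges always ride at
the cut and an effect of this size is not FDR-detectable at n = 20+20 —
the hub structure is what makes the planted contract ("recoverable in at
least 80% of replicates") achievable, and mirrors the hub-like character of
the regions the analysis is designed to flag.

**Hidden regimes.**  A six-ROI subset (default: the six planted regions
above, mirroring a study design in which the abnormal regions are exactly
the ROIs taken into the dynamic stage) follows a regime-switching VAR(1): a first-order
Markov chain with symmetric switch probability 1/dwell (mean dwell 100 TR)
selects between two directed coupling matrices — rings of opposite
orientation and partly opposite sign, magnitude 0.65 (spectral radius 0.63,
stationary).  Matched magnitudes give every node the same variance
inflation in both regimes, so a subject's FC does not depend on regime
occupancy.  The VAR innovations are the subset's own correlated background
filtered to a wider band (0.01–0.20 Hz by default): strictly narrowband
innovations make 22-sample lag-1 regressions ill-conditioned (windows are
near-sinusoidal, so the lagged regressors are collinear), biasing path
coefficients toward zero and roughly doubling their sampling noise — with
them the planted regimes are not separable at the study's window length.
This is a deliberate deviation from "everything strictly in-band" and the
single place where the generator trades spectral fidelity for
identifiability.

**Calibration.**  With effect_size 0 and no coupling the two groups are
exchangeable; the measured type-I error of the adjusted group test across
nodal AUC families is ~0.02–0.09 at alpha 0.05 (slightly conservative
because AUC values are correlated across nodes).  Dwell 100 TR keeps the
fraction of regime-mixed windows near 20%; windows straddling a regime
boundary are genuinely ambiguous and bound the achievable window-label ARI
at roughly 0.9.

## Numerical choices

- Edge-count rounding: round-half-up of s·N(N−1)/2.
- Fisher z clips |r| ≥ 1 to 1 − 1e-7 (exact duplicates of a column).
- OLS via `numpy.linalg.lstsq`; coefficient standard errors from
  s²·diag((XᵀX)⁻¹) with the usual dof correction.
- k-means restarts draw initial centroids uniformly without replacement;
  determinism comes from a single `numpy` Generator per fit.
- Null-network rewiring runs igraph's degree-preserving rewire with the
  Python `random` module seeded per call (state saved and restored).
- All user-facing node indices are 1-based (AAL convention).
- Stage seeds derive from the master seed as CRC32(stage name) XOR seed,
  truncated to 31 bits.

## Problem sizes used by the shipped checks

The analysis drivers run the full study dimensions (40 subjects, 25-point
grid, 100 nulls).  The test suite and acceptance script use the same cohort
dimensions but 20-null ensembles for the single-network small-world checks,
10–20 k-means restarts, 25 replicates for node recovery, and 200
metric-level tests for null calibration; these sizes were chosen so each
recovery statistic is estimated with enough replicates to be stable while
the whole suite stays desk-scale.

## Known limitations

- Pairwise GC cannot distinguish direct from mediated influence; a
  conditional (multivariate) variant is out of scope.
- The hybrid L1/mean k-means has no Lyapunov function; the squared-error
  trace is asserted non-increasing on the shipped data but is not
  guaranteed in general.
- Occupancy is the only state-dynamics statistic; dwell times and
  transition matrices are not computed.
- Real cohort-level findings (which regions are abnormal in actual JME)
  are cohort-dependent and are reproduced here only as planted effects on
  synthetic data.
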