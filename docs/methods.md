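# Methods

This note documents the models, defaults and design choices behind
`fcdyn`, and what the synthetic validation does and does not establish.

## Synthetic session generator (`fcdyn.simkit`)

Ground-truth networks are directed weighted graphs with an exact edge
count `round(density · n(n−1))`, weights uniform in a configurable range
(default 0.3–0.8). Signals come from a stable MVAR process: the edge
weight i→j is placed at the lag-1 cross coefficient (split evenly across
lags when order > 1), with a lag-1 self-decay of 0.5 on the diagonal and
identity innovation covariance scaled by `noise_scale²`. This is the
simplest generative structure whose directed ground truth is recoverable
by all four measures, and the identity innovation covariance avoids
confounding instantaneous correlation with directed coupling.

Stationarity is enforced by uniformly shrinking all coefficients until the
companion-matrix spectral radius is ≤ 0.95 (checked by eigendecomposition;
an error names the offending block if shrinking fails). Each block discards
a 1000-sample burn-in so the retained segment is stationary. Sessions
concatenate per-task blocks (distinct networks per task) with half-open
annotations in seconds. Optional 1/f-shaped additive observation noise is
available but off by default so the recovery oracles stay exact.

What the generator emulates: 1000 Hz multichannel signals with directed,
task-dependent linear coupling. What it does not: nonlinear/nonstationary
neural dynamics, volume conduction, artifacts, epileptiform activity, or
realistic spectral content beyond the AR structure. Perfect scores on this
surrogate therefore demonstrate correctness of the estimation machinery
under the model's own assumptions, not expected performance on patient
recordings, where accuracies below 1 are the norm.

Default study conditions used in the tests and the acceptance script:
three tasks × 60 s blocks, 10 channels, density 0.2; fusion tuning uses
10-node networks at 20 000 samples (5 train / 5 held-out) and transfer is
checked on 30-node networks at 10 000 samples, 5 seeds. These sizes keep
the full validation suite to a few minutes while leaving each statistical
check well-powered.

## Connectivity measures (`fcdyn.fcmeasures`)

Every window is linearly detrended and z-scored per channel before any
measure; this removes slow drifts and makes all outputs invariant to
channel scaling. Bipolar derivation (adjacent-contact subtraction) is
applied when pairs are supplied, since intracranial FC is conventionally
computed on bipolar channels.

- **BCorrU**: absolute Pearson correlation; zero-variance channels yield
  zero entries with a logged warning.
- **BCorrD**: maximum absolute lagged correlation over lags 1..L (default
  L = 100 ms · fs), direction assigned winner-take-all (the weaker
  direction is zeroed). The underlying description is a comparison of
  predictive power, not a formula; this operationalization is the
  package's documented choice.
- **MVAR fit**: multichannel least squares on the lagged regressor matrix;
  near-singular Gram matrices fall back to a small ridge with logged
  strength. Order selection ("auto") minimizes BIC
  `ln|Σ_w| + (ln N / N) p n²` over p = 1..max_order (default 10 at the
  operation level; the sliding-window pipeline uses max_order 5, ample for
  the order-1 generator while halving fit cost).
- **COH1 / PDC**: evaluated from `Ā(f) = I − Σ_k A_k e^{−i2πfk/fs}` on 64
  equispaced frequencies in 1–45 Hz and reduced to one matrix by the band
  mean. Band and aggregation are package defaults (a broadband mean is the
  least-assumption reduction); both are parameters. PDC's textbook
  (target, source) indexing is transposed at the module boundary so every
  matrix in the repository is source-row → target-column.

## Fusion and GA tuning (`fcdyn.fusion`)

The fused score is a convex combination of logistic memberships,
`Σ_m α_m σ(k_m(M_m − θ_m))` — monotone in every measure, bounded in [0, 1],
and differentiable in its parameters. Undirected measures (BCorrU, COH1)
contribute symmetrically to both directions.

The genetic algorithm tunes 12 parameters (per-measure θ, k, α).
Fitness is the mean edge-detection AUC against the simulated ground truth;
AUC is threshold-free, so no decision cutoff needs committing during
tuning. Defaults: population 50, 40 generations, tournament selection
(size 3), one elite (making the running-best trace non-decreasing by
construction), uniform crossover (rate 0.7), Gaussian mutation (rate 0.2,
sd 0.1; slope genes use a 20× wider sd to match their scale). Measure
matrices are precomputed per training network, so a genome evaluation is a
re-fusion plus an AUC — the GA costs seconds. An all-identical population
triggers an early stop with a warning.

## FC dynamics (`fcdyn.dynamics`)

Windows are half-open `[k·hop, k·hop + w)` anchored at 0 s, default
w = 5 s, 50% overlap. A window wholly inside one annotation takes its
label; boundary-straddling windows are labeled "mixed", kept in the FCD
but excluded from clustering/classification (how boundary windows should
be labeled is genuinely open; exclusion is the conservative choice). FCD
correlates the off-diagonal FC entries (the diagonal is identically zero
and would distort the correlation) of the raw fused weights — not
binarized matrices. Constant-FC windows get zeroed FCD rows with a logged
warning.

## Task states and metrics (`fcdyn.taskstates`)

Spectral clustering uses a Gaussian affinity with the median-pairwise-
distance kernel-width heuristic and 10 seeded k-means restarts; BIRCH uses
scikit-learn's CF-tree with agglomeration to k. t-SNE (PCA init, fixed
seed) is for inspection only.

The evaluation metrics are implemented from their definitions (pair
counting over all W(W−1)/2 pairs, entropy-based MI with the arithmetic
normalization, hypergeometric-expectation-adjusted Rand); scikit-learn's
implementations serve as an independent cross-check in the tests. Two
documented deviations from the source formulas:

- The printed balanced-accuracy formula contains apparent typos (a
  precision term where a recall belongs, and an undefined "PN" count); the
  implemented BAS is standard balanced accuracy — macro-averaged recall —
  the quantity the named scikit-learn metric computes.
- "RI = ACC" conflates two quantities. For clusterings, accuracy requires
  aligning cluster labels to classes; the package reports pair-counting RI
  and Hungarian-matched accuracy separately.

MAE on categorical labels uses the integer encoding in annotation
(first-appearance) order and is flagged as encoding-dependent in the
report metadata.

Classification uses stratified, time-separated 5-fold CV: each class's
windows are cut into K contiguous time segments, fold f tests on segment f
of every class, and training windows whose time span overlaps any test
window are dropped (with 50% overlap, the windows adjacent to each split
boundary). This keeps fold class proportions within one window of the
global proportions while guaranteeing no train/test sample overlap in
time. How to order time-contiguity against stratification for interleaved
tasks is unstated in the underlying design; the contiguous-segment-per-
class rule is this package's documented choice. Classifiers: random forest
(500 trees, fixed seed) and RBF-SVM (C = 1) on features z-scored using the
training fold only. Metrics are aggregated by concatenating predictions
across folds; a label-permutation control verifies chance-level behavior.

## Region profiles (`fcdyn.netprofiles`)

Region mapping takes the maximum FC weight over all channel pairs per
directed region pair and discards within-region links; it is idempotent
under channel duplication. Path-based centralities convert weights
w ∈ (0, 1] to lengths 1/w (stronger link = shorter path — the standard
convention for connectivity weights; the alternative 1−w compresses strong
links). Degree is weighted strength normalized by R−1 (whether "number of
links" meant binary counts is ambiguous; weighted strength preserves
information, and an optional threshold exists for binary degree).
Closeness uses the reachable-fraction scaling
`((r−1)/Σd) · ((r−1)/(n−1))` so disconnected graphs stay in [0, 1];
betweenness is normalized by (n−1)(n−2). Katz solves
`x = α M x + β·1` directly (M = Aᵀ for incoming walks, A for outgoing)
with α = 0.9/λ_max, β = 1, rescaled to max 1; the printed constraint
"α < (λ_max − 1)" is read as the convergence condition α < 1/λ_max. For
nilpotent (acyclic) adjacency, where λ_max = 0 and the walk series always
terminates, the attenuation fraction is used as α directly. All seven
metrics are bounded in [0, 1] by construction, so profile axes need no
further standardization. Closeness and betweenness are delegated to
networkx; Katz and degree are direct computations (networkx's
power-iteration Katz would not meet the 1e−10 exactness contract, which is
verified against an independent dense solve).

## Between-task comparisons (`fcdyn.taskcompare`)

Link classification thresholds — "strong" median ≥ 0.5 and Wasserstein
boundary 0.2 — are declared package defaults (exposed as parameters), kept
consistent with the median ≥ 0.5 highlight convention; the original
analysis does not print its cutoffs. The Mann–Whitney test uses exact
enumeration for m+n ≤ 12 without ties and the tie-corrected normal
approximation otherwise; fully tied samples return p = 1 with a warning.
No multiple-testing correction is applied by default, matching the raw
p < 0.001 rule of the degree-contrast highlighting (a Bonferroni option
exists at the analysis level). The highlight rule is a pure function of
(medians, p-values) and is tested on an exhaustive boundary grid.

## Numerical and reproducibility notes

- One global seed per run fans out to stage seeds by fixed offsets;
  identical inputs give bitwise-identical simulator output and identical
  reports.
- Matrix orientation (source row → target column) is a single repository-
  wide convention, asserted at the PDC boundary where the textbook
  convention differs.
- Degenerate inputs (zero-variance channels, constant FC windows, empty
  graphs, fully tied samples) degrade to defined values with logged
  warnings rather than NaNs.

## Known limitations

- The fuzzy-fusion rule base is a concrete monotone realization
  (memberships + learned convex weights) of an ensemble architecture whose
  published description leaves the exact rule base open.
- Linear-Gaussian surrogates make the four measures near-ideal; the
  validation bounds implementation error, not method error on real data.
- Group-level pooling concatenates per-window region metrics across
  sessions sharing a region label — pooling, not mixed-effects modelling.
- EDF files are read (via mne) but not written; the native container is
  npz + JSON sidecar.
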