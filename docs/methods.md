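# Methods

## Synthetic data model

The generator plants every quantity the pipeline later estimates.

**Block-correlated beta series.**  Trial amplitudes follow a
one-common-factor construction

    x_i(t) = sqrt(b)·g(t) + sqrt(w − b)·f_{block(i)}(t) + sqrt(1 − w)·e_i(t)

with g, f, e independent standard normals.  The population correlation is
exactly `w` (`within_r`) inside a block and `b` (`between_r`) across
blocks, and the implied covariance is positive semidefinite for any
0 ≤ b ≤ w < 1 — which is why this construction was chosen over sampling a
target correlation matrix directly.  Defaults: 100 nodes, 4 stable blocks
of 22 nodes, 12 movers, `within_r = 0.5`, `between_r = 0.1`, 40 trials per
condition.  The trial count matches a realistic per-condition beta-series
length after QC (high thirties), and the block contrast is strong enough to
be recoverable from 40 trials yet weak enough that consensus clustering is
doing real work (single Louvain runs at unlucky costs do misassign nodes).

**Movers.**  Four task conditions are modeled (spatial/temporal ×
encoding/retrieval).  Half of the mover nodes switch blocks between
encoding and retrieval, half between spatial and temporal conditions, with
block pairs cycling so movers do not share one reassignment pattern.
Non-movers keep one block label everywhere; this invariant is enforced at
construction.

**BOLD.**  Node time series are Σ_trials amplitude × (boxcar ⊛ canonical
HRF) plus white noise.  The canonical HRF is the conventional double gamma
(response shape 6, undershoot shape 16, undershoot ratio 1/6, unit peak);
the default kernel spans 32 s.  Trial schedules use 6 s trials on a 1.6 s
repetition-time grid with 1–3 s jittered inter-trial intervals.

**Motion and behavior.**  Framewise displacement is a constant baseline
plus Bernoulli spikes.  Behavioral performance is
`clip(intercept + slope·similarity + noise, 0, 1)` with defaults
intercept 0.9, slope −0.5, noise sd 0.02 — a planted *negative* coupling
between encoding-network similarity and retrieval performance.

**Cohorts.**  `simulate_similarity_cohort` draws each subject's `within_r`
uniformly from (0.3, 0.6).  This between-subject heterogeneity in
connectivity strength is what spreads the measured encoding-network
similarities across subjects (sd ≈ 0.1); without it, similarity would vary
only by trial-sampling noise and a similarity→behavior slope would be
practically undetectable at n = 18.  The resulting effect size (|r| ≈ 0.6+)
is in the range typically reported for such brain–behavior correlations.

**What the generator does not emulate:** spatial autocorrelation,
physiological noise spectra, scanner drift, hemodynamic variability across
regions, or spatially clustered communities (node coordinates are random
within a 160 mm cube, subject only to a minimum 8 mm separation so the
20 mm edge filter has work to do).  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated statistical model,
not robustness to real fMRI artifacts.

## Pipeline conventions and numerical choices

- **FD exclusion** compares each volume's displacement against the fixed
  0.55 mm threshold; a trial is dropped iff any volume in
  [onset, onset + duration) exceeds it.  The screened window defaults to
  the modeled 6 s trial duration and is configurable.
- **Beta estimation** is least-squares-all: one GLM containing every trial
  regressor simultaneously, solved by `lstsq` for all nodes at once.
  Rank-deficient designs are rejected with the offending columns named
  (QR diagnostic).
- **Fisher transform**: r numerically at ±1 is clipped to ±0.999999 with a
  warning before artanh.
- **Filter order** is fixed: Fisher → drop negatives → drop < 20 mm edges
  → (optional) cost threshold.  Averaging to group level happens on the
  filtered Fisher-z matrices.
- **Cost** is the *removed* fraction of currently nonzero edges
  (higher cost ⇒ sparser); the weakest ⌈cost·E⌉ edges are zeroed with ties
  at the cut broken by (i, j) lexicographic order, making the surviving
  edge sets nested across costs and the operation deterministic.
- **Louvain** maximizes Q(γ) with γ = 1.25 at *every* clustering call,
  including re-clustering of consensus matrices, for single-parameter
  consistency.  The greedy phase only accepts strictly positive gains, so
  the returned Q never falls below the all-singletons start.  Node sweep
  order is shuffled from the seed; the implementation is jit-compiled
  because consensus clustering multiplies it by iterations × costs ×
  rounds (≈ 0.2 ms per run on a 100-node network).
- **Consensus** iterates (cluster n times → co-assignment matrix →
  zero < τ = 0.5 → re-cluster) until the co-assignment matrix is
  block-binary, capped at 20 rounds.  A block-binary matrix's connected
  blocks are extracted directly (they are exactly the agreed partition).
  The cross-cost consensus applies one final Louvain pass by default; a
  connected-components extraction is exposed as an alternative
  (`final="components"`) since both resolve identically on clean data.
- **Per-iteration seeds** are derived arithmetically from the config seed
  (`seed+1 … seed+n` within a round; per-cost base seeds offset by
  100 000), making every partition bit-reproducible.
- **Cost grid**: {0.01, 0.11, …, 0.91} — ten values spanning near-full to
  very sparse networks.
- **Movers** are operationalized as the cells of the meet (common
  refinement) of the condition partitions smaller than
  `min_stable_size = 5`.  Mover identification is performed on group-level
  (cohort-averaged) networks: single-subject 40-trial matrices carry
  enough sampling noise that a stable node is occasionally genuinely
  misassigned in one condition (its empirical connectivity really is
  stronger to another block), while 18-subject averages make stable-node
  misassignment vanishingly rare.
- **z-score** uses the population standard deviation within each module;
  modules with zero spread give z = 0 for all members.  PC of an isolated
  node is 0.  PC is additionally z-scored across nodes (its raw
  distribution is narrow); identity thresholds sit at 0 on both axes.
- **Fragmentation** counts co-module membership (largest number of the
  RSN's nodes sharing one data-driven module), not graph connectivity
  inside the module; computed as (T − C)/T to avoid float residue.
- **NMI** is normalized by the arithmetic mean of the entropies (natural
  logs); two single-cluster partitions are defined as identical (NMI 1).
  The NMI-vs-cost AUC is a trapezoid integral divided by the grid span, so
  a constant curve's AUC equals that constant and values are comparable
  across grids.
- **Similarity** correlates strictly-upper-triangle entries; subnetwork
  similarity restricts to the induced submatrix first.  Constant edge
  vectors raise a "degenerate similarity" error; the cost sweep converts
  that error into a missing (NaN) row rather than failing.
- **Bonferroni** multiplies the raw p by the number of condition pairs
  (default 6) and caps at 1.  The cost-sweep correlations are reported
  uncorrected by design (a descriptive robustness curve).
- **Regression/AIC**: OLS via statsmodels; AIC under the Gaussian
  likelihood convention including the constant, so ΔAIC between two
  reports is internally consistent (absolute AIC values are convention
  dependent).  Exactly collinear features are rejected by a rank check
  that names duplicated columns.
- **Lasso** standardizes features internally and solves
  (1/2n)‖y − Xβ‖² + λ‖β‖₁ per grid value, so for mutually orthogonal
  standardized columns the solution equals the soft-thresholded OLS
  coefficient and λ = 0 reproduces OLS.  The default grid is 100
  log-spaced values from λ_max (smallest λ zeroing all coefficients)
  down to λ_max·10⁻⁴.  Last-survivor ties go to the smaller column index
  and are logged.
- **ANOVA** is a two-way fixed-effects decomposition (balanced layouts
  only; unbalanced input is an error).  An exactly constant response —
  where every sum of squares vanishes and F is 0/0 — is defined as
  F = 0, p = 1.  Post hocs compare subnetwork marginal means, paired by
  subject when a subject column is present, Bonferroni adjusted.

## Test-scale choices

The recovery suites run at the default fixture scale: 20 seeds for
planted-partition and mover recovery (the latter on 18-subject group
averages per condition), 50 cohort seeds for the behavior-slope recovery,
and 10,000 null cohorts for the family-wise false-positive estimate —
a sample large enough that the Monte-Carlo standard error (≈ 0.002) is
small relative to the 0.05 bound being verified.  Null cohorts reproduce
the dependence structure of the real comparison family: the six pairwise
similarity vectors share per-condition subject factors, which is precisely
the setting in which Bonferroni is conservative.

## Known limitations

- Louvain is greedy and stochastic; only for ≤ 8-node fixtures do tests
  compare against the exhaustive modularity optimum.  On larger networks
  quality is cross-checked against networkx's implementation.
- The baseline (residual time-series) path shares the GLM machinery but
  its window boundaries are user-supplied; no automatic block detection.
- No overlapping or temporal (multilayer) community structure; partitions
  are hard assignments.
- The behavior model is linear with homoscedastic noise; no robust
  regression or cross-validated penalty selection.
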