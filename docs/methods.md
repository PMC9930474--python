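# Methods

This note documents the models, numerical choices and limitations of the
`mouseconn` pipeline: what each stage assumes, which parameters matter and
why their defaults were chosen, and what the synthetic-data generator does
and does not emulate.

## Synthetic cohorts

The generator emulates the geometry of a chronic-cannabinoid imaging
study in aged mice: three treatment groups (placebo, CBD, THC) of 7–8
subjects, two imaging sessions (end of chronic exposure; two-week
washout), 148 bilateral ROI nodes, 200 time points at a 1 s sampling
interval.

Each subject-session block is drawn from a zero-mean multivariate normal
whose correlation matrix is block-constant: `within_module_corr` (default
0.5) inside planted modules, `between_module_corr` (default 0.1)
elsewhere. This is deliberately the simplest generative law with
controllable modular structure; it makes the planted partition the
population optimum of modularity maximization on thresholded correlation
graphs. On top of the correlated draw the generator adds white noise
(`noise_sd`, default 0.2), a per-node linear drift (`drift_amplitude`,
default 0.5, slope uniform in ±1 across nodes over a centred unit ramp),
and Poisson-placed motion-spike frames (`spike_rate`, default 2 expected
frames/series) whose values are offset by 5–10 noise SDs with random
sign per node; spike frames are recorded as censoring ground truth.

Defaults and rationale:

- **8 planted modules** of ~18 nodes. Resting-state parcellations
  typically decompose into roughly 6–10 functional communities. Module
  geometry also controls where on the 2–40 % density ladder between-module
  edges start competing with within-module edges: with 8 modules the
  within-module pair fraction is ~11 %, so most of the ladder is sensitive
  to the balance of within- versus between-module weight. (With only 4
  large modules that fraction is ~25 % and most of the ladder carries no
  group information — a design flaw found and corrected while building the
  generator.)
- **Effect multipliers** map (group, session) to a factor on the
  within-module correlation; the only non-unit default is (CBD, washout) =
  1.3 (within-module r 0.5 → 0.65, capped at 0.99). This plants the one
  robust group effect the connectome analysis is designed to detect —
  increased network modularity in the CBD washout group — at a strength
  detectable with 8 subjects/group (a 20-cohort pilot gives a ~9-sigma
  cohort-level contrast).
- **Measure tables**: values are `baseline × (1 + shift) + N(0, (cv·baseline)²)`
  with cv = 0.05. The default volume effect applies −12.17 % (THC,
  chronic) and +10.24 % (THC, washout) to a designated 7-ROI
  "dopaminergic subsystem" (mirroring VTA, substantia nigra,
  caudate/putamen, olfactory tubercles, ventral pallidum, accumbens core
  and shell); FA baselines are N(0.4, 0.05), a typical placebo range for
  regional FA, with washout FA reductions (−15 % THC, −8 % CBD).
- Node count defaults to 148 (the connectivity parcellation) and is
  configurable to 139 (the volumetry atlas); both parcellations appear in
  this study design and the analysis is agnostic to which is used.

What the generator does **not** emulate: hemodynamics, spatial structure
(no voxel-level signals; atlas label placement is random), realistic
mouse anatomy, physiological noise spectra, and session-to-session
subject correlation (sessions are independent draws). Passing recovery
tests therefore demonstrate that the analysis chain detects planted
covariance structure at realistic n, T and effect size — not that it is
robust to all artifacts of real acquisitions.

All randomness descends from a single root seed via `SeedSequence` spawn
keys hashed from (group, subject, session), so cohorts are reproducible
element-for-element and insensitive to generation order.

## Preprocessing

Default stage order: spike censoring → detrend → band-pass → (nuisance
regression when a design is supplied) → L2 normalization.

- **Spike detection** uses the cross-node mean absolute successive
  difference, robust-z-scored against its median/MAD (consistency factor
  1.4826), threshold `z_cut = 4`. A transient spike produces two large
  successive differences; the trailing recovery edge is attributed back to
  the spike frame by checking whether the signal returns to its pre-spike
  level on the same robust scale. The statistic and threshold are this
  package's declared choice; motion-outlier detection conventions vary
  across toolchains.
- **Censoring, not interpolation**: censored frames are excluded from
  every fitted coefficient (detrend, nuisance) and from correlations. The
  single exception is the frequency-domain filter, which needs values on
  the full grid: censored frames are linearly interpolated from good
  neighbours *for the filter input only*, and remain censored afterwards.
- **Band-pass** is a hard mask on the real-FFT bins, keeping
  [0.01, 0.1] Hz; zero-phase and exactly idempotent. In the default chain
  the component of the linear ramp that leaks through the mask is also
  projected out (`consistent_detrend`), which makes detrend → band-pass a
  single orthogonal projection; the full chain is then exactly idempotent
  on uncensored data. With censored frames, re-running the chain moves
  values only through interpolation boundary effects (empirically < 5 % of
  signal scale). An alternative high-pass/low-pass pair (0.009 / 0.12 Hz)
  is reachable through the same function's parameters.
- **Nuisance regression** is OLS of each node on [intercept | design],
  fitted on surviving frames, with residuals formed everywhere.
  Rank-deficient designs raise an error naming the offending columns.
  Spike-indicator regressors are redundant under censoring and are not
  added by the default chain.

## Connectivity and thresholding

Pearson r over surviving frames; Fisher z = atanh(r) with |r| clipped to
1 − 1e−12; the z diagonal is stored as 0 and excluded from analysis.
Edge significance uses a percentile bootstrap of frame resamples (B =
1000, α = 0.05 by default): an edge is significant when the central
1 − α interval of resampled correlations excludes zero. Degenerate
(zero-variance) resamples contribute r = 0.

Negative correlations are discarded before graph analysis (configurable
to absolute value): the weighted strength/clustering formulas assume
nonnegative weights and the study design interprets edges as connection
strength. Proportional thresholding keeps the k = ⌊d·N(N−1)/2⌋
largest-weight edges with ties broken by (i, j) lexicographic node order,
which makes thresholding deterministic and the density ladder nested.
Thresholded edges keep their z weights (weighted, not binarized,
analysis).

## Graph metrics

- Clustering uses the geometric-mean (Onnela) normalization on
  max-normalized weights, so per-node values live in [0, 1]; an
  arithmetic (Barrat-style) variant is available. Transitivity is the
  global triangle-to-triplet ratio on the same normalized weights.
- Path metrics run Dijkstra on edge lengths 1/w; CPL averages over
  connected ordered pairs and is undefined (error) on fully disconnected
  graphs, while efficiency averages 1/d with 1/∞ = 0 and is always
  defined.
- Assortativity is the Pearson correlation of endpoint strengths over
  both orientations of every edge; uniform-strength graphs return 0 with
  a warning.
- Eigenvector centrality is power iteration to 1e−10 on the largest
  connected component (zeros elsewhere, with a warning); betweenness uses
  shortest paths on 1/w lengths.
- Modularity is maximized by a seeded Louvain procedure (random node
  order per sweep, greedy gain moves, graph aggregation with self-loops
  carrying within-community weight). The reported Q is always recomputed
  from the original graph and affiliation by a standalone evaluator. The
  consensus partition over n restarts reports the median module count and
  the restart whose (count, Q) is closest to the medians; an
  association-matrix consensus (co-assignment frequencies thresholded at
  τ = 0.5) is available as an alternative. The resolution parameter is
  fixed at γ = 1.
- Null models perform swaps-per-edge × |E| weighted double edge swaps
  ((a,b),(c,d) → (a,d),(c,b), each keeping its weight), which preserves
  the binary degree sequence and the weight multiset exactly; strength
  sequences are preserved only in distribution. The small-world index is
  (CC/CC_null)/(CPL/CPL_null) with null means over 10 rewired graphs.
  Note the λ/γ naming convention used in parts of this literature
  attaches λ to the clustering ratio and γ to the path-length ratio —
  reversed relative to the Watts–Strogatz convention; the formula
  implemented is the ratio written above.
- The density sweep evaluates global metrics at 2–40 % in 2 % steps and
  integrates each curve by the trapezoidal rule over density. Densities
  where a metric is undefined (e.g., CPL on an empty 2 % graph)
  contribute NaN and are excluded from that metric's integral. Per-density
  modularity defaults to a single seeded maximization (`q_iters = 1`):
  the consensus rule exists to stabilize the *community affiliation*
  reported for a network, whereas the sweep needs only the Q statistic,
  whose restart-to-restart spread is far below the group contrasts of
  interest; consensus Q per density is available via `q_iters`.

## Regional statistics

Volumes are voxel count × unit voxel volume (mm³); normalization divides
by the subject's total labeled volume so fractions sum to 1. The paired
percent-difference analysis expresses two matched volumes as
complementary percentages of their sum (they add to 100 exactly) before a
paired t-test.

Group tests: Kruskal–Wallis (tie-corrected, χ² p on k−1 df) for 3+
groups; Mann–Whitney U with exact enumeration for n₁+n₂ ≤ 12 and the
tie-corrected normal approximation otherwise; one-way ANOVA with

    ω² = (SS_between − (k−1)·MS_within) / (SS_total + MS_within)

reported unclamped (negative values are informative about near-null
effects); two-way treatment × session ANOVA with Type-II sums of squares
for unbalanced layouts (interaction dropped with a warning when a cell is
empty).

The rank-based FDR filter sorts p-values ascending and compares p(i)
against i·q/(V·c(V)) with q = 0.2 and c(V) = 1 by default; V is the full
comparison count (139 regions) even when fewer tests are supplied.
Decisions use the pointwise rule (a test passes iff its own p is at or
below its rank's critical value); display rounding is fixed at 3
decimals to match regional-table conventions. The adaptive two-stage
step-up procedure (for node-level statistics) runs a first linear
step-up at q/(1+q) to estimate the true-null count m₀, then a second
step-up at (q/(1+q))·(m/m₀); it agrees decision-for-decision with the
standard two-stage implementation in statsmodels.

Degenerate inputs have explicit conventions: identical paired vectors
give (t = 0, p = 1); constant nonzero paired differences raise; all-equal
Kruskal–Wallis input gives (H = 0, p = 1); constant investigation ratios
raise.

## Problem sizes used in the test suite

Unit tests run on graphs of ≤ 30 nodes with brute-force oracles at
≤ 12 nodes. The end-to-end recovery check simulates 100 cohorts of 2
groups × 8 subjects (148 nodes, 200 time points) and compares group mean
modularity AUCs; bootstrap calibration uses 1000 independent pairs at
n = 200, B = 1000; null-model contracts use 50 random graphs plus 20
ring-lattice seeds at N = 100. These sizes were chosen to estimate each
property's rate with enough replicates for a stable pass/fail margin
while keeping the whole suite runnable on a laptop-class single core.

## Known limitations

- Sessions of one subject are independent draws; no within-subject
  covariance or repeated-measures structure is planted, so mixed-model
  analyses cannot be validated against this generator.
- The bootstrap edge-significance test shares one frame-resampling index
  matrix across pairs of a series (preserving cross-node structure within
  a resample); per-pair independent resampling is available through the
  single-pair function.
- The spike model produces single-frame outliers; sustained motion
  (multi-frame drifts) is only partially covered by the recovery-edge
  logic.
- Louvain is a greedy heuristic; on ambiguous graphs single runs can land
  in local optima ~0.05 Q below the best known partition. The consensus
  procedure and the restart envelope diagnostics (`all_q`) exist to make
  this visible.
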