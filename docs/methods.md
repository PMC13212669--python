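# Methods

## Model and procedure

For gene g and sample i, the analysis models log2-counts-per-million

    y_gi = log2((c_gi + 0.5) / (R_i + 1) × 1e6)

with R_i the **upper quartile** of sample i's counts (type-7 / linear
order-statistic interpolation; the convention is fixed so results are
bit-stable).  With these offsets the y values are not literally "per
million reads", which is irrelevant for selection and testing.  Each gene
follows a Gaussian linear model `y_g = X β_g + ε_g`,
`ε_gi ~ N(0, σ_g²/w_gi)`, where X contains an intercept, the primary
variable blocks (never subject to selection), and the candidate covariate
blocks.  Categorical variables contribute L−1 treatment indicators against
the first declared level.  Gene filtering (minimum mean count and maximum
zero count, e.g. mean ≥ 8 with at most 27 zeros out of 31 samples for
typical bulk data) is an explicit, optional preprocessing step — never
applied silently — and library sizes are computed on the filtered matrix.

**voom weights.** A first unweighted pass yields residual standard
deviations s_g and fitted values.  A LOWESS curve (span 0.5, 3 bisquare
robustness iterations, delta = 1% of the x-range — the classical defaults)
of s_g^{1/2} on the mean log-count c̃_g gives the mean-variance trend;
each observation's weight is `trend(fitted log-count)^-4`, with the trend
linearly interpolated, constantly extrapolated beyond the observed c̃
range, and floored at 1e-6 before the −4 power.  One weighted refit
follows (a single voom pass).  Within a backward-selection run the voom
weights are recomputed for **every** reduced model; c̃_g does not depend
on the design, so the LOWESS neighborhoods are precomputed once per
dataset (see *Numerics*).

**Moderated tests.** Residual variances are shrunk toward a scaled-F
prior: `s̃_g² = (d0·s0² + d·s_g²)/(d0 + d)`.  The prior (d0, s0²) is
estimated by moment matching on log s² (digamma/trigamma matching;
trigamma inverted by Newton iteration).  Non-positive excess variance
yields d0 = ∞ (complete pooling); if every s_g² is identical the prior is
returned as that common value.  Single-column blocks use moderated t with
d0 + d degrees of freedom; multi-column blocks use a moderated F
comparing the full fit with the block-dropped fit, the shrunken variance
in the denominator.  d0 = 0 reproduces classical per-gene tests exactly
(verified against brute-force regression), and the whole pipeline
reproduces R limma's `voom` + `eBayes` to ≲0.2% in weights and ≲1e-3 in
p-values on shared inputs (cross-checked in the test suite).

**Relevance and backward elimination.** A candidate's relevance is
`r = #(p ≤ 0.05) / max(#(p ≥ 0.75)/5, 1)` over its per-gene p-values
(raw, not q-values; both comparisons inclusive).  The least relevant
candidate is removed at each step — ties broken by declaration order so
runs are deterministic — until none remain.  `select_at(path, λ)` scans
the removal sequence and stops at the first removal with r ≥ λ; the
selected set is that suffix.  This stop-at-first rule makes |S(λ)|
nonincreasing in λ even though the recorded r sequence need not be
monotone.

**Pseudo-variable FSR calibration.** For b = 1..B, k_P pseudo-variables
are appended and the elimination rerun.  Generators:

- WN — i.i.d. N(0, 1) entries;
- RX — k_P randomly chosen columns of the *candidate* design block with
  one shared random row permutation (primary-variable columns are excluded
  from the pool, so permuted copies of the primary signal are never
  injected; switchable);
- OWN / ORX — the above projected by (I − H), H the projector onto the
  intercept-augmented full design, giving exactly zero sample means and
  correlations with every design column.  Requires
  rank(X) + k_P ≤ n − 1.

With Ī*_P(λ) and S̄_P(λ) the across-b means of selected-pseudo and total
selected counts, the estimators are
`α̂_RE,P(λ) = Ī*_P/(1 + S̄_P)` and `α̂_ER,P(λ) = Ī*_P/(1 + S(λ))` with
S(λ) from the original path.  The curves are step functions, so the λ grid
is the sorted union of every recorded r value plus 0 — lossless, and
refining the grid cannot change the answer (property-tested).  Given the
target α0 and the unknown irrelevant count k_I, the cut-offs are
`c = k_P·α0/(k_P·α0 + k_I)` (RE; algebraically consistent with inverting
the pseudo-FSR identity back to α0) and `c = k_P·α0/k_I` (ER).

**k_I fixed point.** k_I is initialized at the number of candidates
(everything irrelevant), then iterated: compute c, take λ̂ as the smallest
grid value with α̂(λ̂) ≤ c ("inf over a step function" realized as the
smallest qualifying grid point), re-count k_I as the number of unselected
candidates floored at 1, stop when stable or after k_C iterations.  The
iteration scheme is this package's own reconstruction of the estimator
from the published estimating equations; it converges in one or two steps
in practice and recovers the true k_I within ±2 in ≥90% of simulation
replicates.  If no grid point qualifies, λ* = ∞ and the selected set is
empty.

Defaults: α0 = 0.05, k_P = 7, B = 100, mechanism ORX, estimator RE — the
configuration recommended by the simulation evidence (larger k_P gives
better FSR control as long as one residual degree of freedom remains; the
orthogonalized generators behave best when covariates correlate with the
primary variable).  The CLI accepts `--threads`; augmentation sets carry
per-b child seeds, so results are independent of execution order and
parallelism.

## Synthetic data generator

`simulate.build_scenario` / `simulate_counts` invert the analysis model:
draw β, σ², w, then `y = Xβ + ε`, `ε ~ N(0, σ²/w)`, and map back to
counts via `c = round(2^y (R+1)/1e6 − 0.5)` clamped at 0 (nearest-integer
rounding is a fixed choice).  Conditions emulated, with defaults fixed once as a realistic bulk
RNA-seq regime:

- G = 2000 genes × n = 31 samples; a balanced binary primary variable;
  13 candidate covariates (i.i.d. N(0,1)), of which k_R carry signal;
- σ_g² ~ s0²·d0/χ²_d0 with d0 = 4, s0² = 0.25 (log2-scale variances
  mostly 0.1–1, matching what voom fits report on real bulk data);
- weights from a decreasing quarter-root-sd trend in expected log-count,
  clipped to [0.6, 1.2] before the −4 power — the qualitative
  mean-variance shape voom models;
- 80% EE / 20% DE split on the primary variable (exact count); effect
  sizes standardized by the gene's error SD, z·σ_g with z ~ N(0,1), for
  both DE effects and relevant-covariate effects; each relevant covariate
  touches 30% of genes;
- library sizes log-normal around 5×10⁵ so mean counts land in the tens
  (the filtered regime of typical bulk data; average count ≥ 8);
- optionally one relevant covariate constructed with a target correlation
  to the primary variable (default 0.9 when enabled), reproducing the
  confounded regime in which the primary-only model loses FDR control;
- optional categorical candidates (cycled level assignment) to exercise
  the moderated-F block path.

What the generator does **not** emulate: count overdispersion beyond the
Gaussian-on-log-scale approximation, gene-gene correlation, sample
outliers, library-composition artifacts, and single-cell zero inflation.
Passing calibration tests therefore demonstrates correctness of the
selection machinery under the stated model, not robustness to those
violations.

## Numerics

- Per-gene WLS is solved from normal equations assembled with one GEMM
  (`w @ outer(X)`), then a compiled per-gene Cholesky solve that also
  extracts the inverse diagonal (for t standard errors).  Non-positive
  pivots raise rather than silently regularize.
- The LOWESS smoother precomputes sorted order, k-nearest windows, and
  tricube weights for the dataset's fixed c̃ vector; each smoothing call
  is a compiled loop.  It matches `statsmodels` lowess to ~1% of the
  response scale (anchor choice within delta differs slightly) and R's
  `lowess` via the limma comparison above.
- Inside the elimination loop, counting #(p ≤ 0.05) and #(p ≥ 0.75) is
  done by comparing |t| (or F) with the matching reference-distribution
  quantiles — exactly equivalent to thresholding p-values by monotonicity,
  and property-tested against the p-value definition.
- Reduced models in a backward path are column slices of the once-validated
  full design, so rank is checked once per path.
- q-values: Storey step-up `q_(i) = min_{j≥i} π0·G·p_(j)/j` with stable
  sorting for ties; π0 from a 20-bin right-closed histogram (first bin
  whose count does not exceed the mean of the remaining bins starts the
  pooled tail), capped at 1 and floored at 1/G.
- p-values are clipped into (0, 1] at the smallest positive double; an
  exactly-zero coefficient estimate is reported as stat 0, p = 1.
- Degenerate inputs: all-zero sample columns, empty p-vectors, empty
  candidate sets, rank-deficient blocks, and k_P exceeding the residual-df
  budget all raise informative errors.

## Evaluation harness

`evaluation.run_study` scores, per replicate: selection FSR I/(1+S) and
the count of selected truly relevant covariates; and for the downstream
DE analysis the empirical FDR at q ≤ 0.05, the number of true positives,
and the partial AUC at FPR ≤ 0.05 standardized by 0.05 (1.0 = perfect,
0.025 = random).  Aggregates are means with Monte-Carlo standard errors
(SD/√reps).  The empirical FSR is aggregated as the mean of per-replicate
I/(1+S) (the ER functional); strategies compared are the eight
mechanism × estimator variants plus Full (all covariates), LineOnly
(primary only), and Oracle (true relevant set).

The study-scale calibration tests run G = 500, n = 31, 13 candidates,
k_P = 7, B = 20, 50 replicates per scenario with k_R ∈ {0, 2, 6}; the
acceptance script uses G = 1000 and the k_R = 2 scenario.  These sizes
are the package's chosen evaluation defaults; all scale parameters are
arguments and can be raised.

## Limitations

- Backward selection requires rank(X) + k_P < n; for designs wider than
  the sample count only forward-type strategies (with WN/RX generators)
  would apply, and those are out of scope here.
- The FSR guarantee is approximate, resting on the exchangeability of
  pseudo-variables with real irrelevant covariates (checked empirically in
  the tests) and on the fixed-point k_I estimate.
- Covariates are assumed measured without error; hidden-factor adjustment
  (surrogate variables) is not provided.
- With very small G the relevance measure is coarse (integer numerator,
  denominator floored at 1), making r ≈ 1 judgments noisy below a few
  hundred genes.
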