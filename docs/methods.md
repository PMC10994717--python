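# Methods

This note documents the statistical model, the numerical choices and the
limits of what the test suite shows. It complements the README, which
covers usage.

## Data model

Input is long format: one row per subject × visit, a numeric time column,
and mixed-type variables. The workflow assumes a complete dataset —
missing cells are a validation error, not something we impute; users
should impute upstream if needed. `(subject, time)` pairs must be unique,
but visit times need not be aligned across subjects: the spline basis is
continuous in time, so irregular schedules are supported. Type inference
treats numeric columns with at most 9 distinct integral values as
categorical (questionnaire items are commonly small integer scales); the
threshold is configurable and explicit specs always win. Wide tables are
rejected with a hint rather than reshaped, to keep time handling
unambiguous.

## FAMD

The construction is the standard one: continuous column → (x − mean)/sd
(population sd, so each contributes inertia exactly 1); categorical level
ℓ with proportion p_ℓ → (1{x = ℓ} − p_ℓ)/√p_ℓ. SVD of Z/√n gives
eigenvalues λ_k = s_k² with Σλ = #continuous + Σ_j (q_j − 1), training
scores F = Z V with column means 0 and covariance diag(λ). Component signs
are fixed so each component's largest-magnitude loading is positive,
making outputs deterministic. Held-out rows are projected with the stored
training parameters; unseen levels are an error.

Reduction is applied to the **stacked** subject × visit rows, one loading
set serving all time points, so the factor scores keep their longitudinal
structure and feed directly into the mixture model as responses. Per-group
reduction fits one FAMD per named variable group (e.g. per questionnaire
scale), which keeps components interpretable; `n_components="auto"` keeps
the smallest count explaining ≥ 70% of the group's inertia — a stated,
reproducible default, not a claim of optimality. For the simulated
questionnaire data used in the validation runs we instead fix 2 components
per scale: the generator plants exactly one latent factor per scale, so
the first component carries the signal and the second is a buffer;
the indicator expansion spreads noise inertia across many dimensions,
which makes the 70% rule keep ~8 mostly-noise components there.

Covariate regression-out (e.g. age) happens after reduction and before
clustering: each score column is replaced by its OLS residual on the
covariates plus intercept. A rank-deficient covariate design (including
zero-variance covariates) is an error.

## Mixture of spline regressions

- **Time smoother.** Natural cubic regression splines (truncated-power
  natural basis, knots at quantiles of the distinct times), df *including*
  the intercept: df=1 intercept-only, df=2 spans {1, t}, df≥3 adds curved
  terms. Default df=3. With the 3–6 visits typical of cohort studies, any
  low-rank smoother spans essentially the same function space, so an exact
  thin-plate construction would change nothing but the basis
  parameterization; natural cubic splines keep the construction explicit
  and testable. An optional roughness penalty (integrated squared second
  derivative, computed by quadrature on a 2001-point grid) is off by
  default (`penalty_weight=0`).
- **Likelihood.** Gaussian per response, responses independent given the
  component (they are orthogonal factor scores). Subject-level grouping:
  responsibilities are per subject, computed from the product of all the
  subject's visit likelihoods via log-sum-exp (stable for |log density| up
  to ~1e6).
- **EM.** Initialization draws subject responsibilities from a symmetric
  Dirichlet(1); the M-step is per-(component, response) weighted least
  squares with an optional penalty; π_k is the mean responsibility.
  Convergence at relative log-likelihood change < 1e-6, max 200
  iterations; the trace is monotone (tested at 1e-8 tolerance). `n_init`
  defaults to 5 for standalone fits and 1 inside consensus runs, where
  stability comes from the resampling itself.
- **Degeneracy.** A component variance collapsing below `min_variance`
  (1e-10) flags the run degenerate; it is restarted with a fresh sub-seed
  up to 5 times, then raises. There is deliberately no minimum-prior
  pruning: consensus clustering needs a fixed K per run. For
  (near-)noise-free data, where zero residual variance is the correct
  limit rather than a pathology, a positive `variance_floor` clamps the
  variances instead; tests of the zero-noise limit use `1e-6`.
- **Model size.** n_parameters = (K−1) + K·J·(df+1) (df coefficients + 1
  variance per component × response); BIC = −2·loglik + n_parameters·log(#subjects).

MAP assignments break posterior ties toward the lower component index and
are canonicalized (labels 1..K by decreasing cluster size, ties by first
subject), so output labels do not depend on the arbitrary component order.

## Consensus

Per K and repetition: ⌈0.8·n⌉ subjects drawn without replacement (item
subsampling only — no feature subsampling), all their visits retained, the
mixture fitted, MAP assignments recorded. M = co-clustering count /
co-sampling count elementwise; never-co-sampled pairs get consensus 0 with
a warning (at the default fraction and repetitions this indicates
misconfiguration). Final partition: average-linkage hierarchical
clustering of 1 − M cut at K (single/complete/ward available). Defaults:
100 repetitions, fraction 0.8.

Reproducibility: the run for (K, rep) seeds its RNG from the tuple
`(seed, K, rep_offset + rep)`, so results are bit-identical across
processes and two batches with matching offsets merge exactly into the
single-batch result (`merge_consensus`, count-weighted). Degenerate runs
are skipped and reduce the denominators rather than being redrawn, so the
repetition count is an upper bound; the skip count is reported.

## Diagnostics

The consensus CDF uses the strictly-upper triangle (the diagonal's
structural 1s would distort the ascent toward 1), evaluated on a 101-point
grid with trapezoidal area; the delta area is A(K_min) at the smallest K
and (A(K) − A(K−1))/A(K−1) above it. Item-consensus of subject i vs
cluster c averages M(i, j) over members j ≠ i (NaN for a subject's own
singleton cluster). The plain Rand index is computed by pair counting from
the contingency table; the adjusted Rand index (chance-corrected) is
reported alongside and clearly labelled. Diagnostics are emitted as tidy
CSV tables; plotting is left to the caller's tooling.

## Cross-sectional variant

Gower dissimilarity: range-scaled absolute difference for continuous,
0/1 mismatch for categorical, unweighted mean over variables; zero-range
variables are excluded with a warning. Each consensus run computes Gower
on its own subsample (so the continuous ranges are the subsample's), then
cuts an average-linkage tree at K; a small PAM-style k-medoids is
available as an alternative inner clusterer.

## Simulator

The generator emulates a questionnaire cohort: per subject a group, per
scale a random intercept ~ N(0, (0.5·noise_sd)²); the latent value at time
t is intercept + slope(group, scale)·t (+ optional curvature). Group
slopes are spaced `separation` noise-sd apart (default 2.5), increasing
with group index on even scales and decreasing on odd ones, so every pair
of groups is separated on every scale. Continuous items are
loading·latent + N(0, noise_sd²); ordinal items threshold the same
construction into equal-probability bins under the zero-separation
baseline N(0, (loading·0.5·noise_sd)² + noise_sd²) — so under the null the
level frequencies are uniform by construction. In the degenerate
noise_sd = 0 limit the thresholds fall back to equal-frequency quantiles
of the realized values. Defaults: 2 scales, 5 continuous + 5 five-level
ordinal items per scale, 4 visits at t = 0..3, unit noise.

What it does **not** emulate: missing data and dropout, floor/ceiling
effects of real rating scales, correlated residuals across items beyond
the shared latent factor, measurement non-invariance over time, and
unequal visit schedules. Perfect recovery on these simulations therefore
shows the pipeline is correct and stable under its own assumptions, not
that real cohorts will yield clusterings this clean.

## Validation problem sizes

The recovery runs reported by `scripts/acceptance.py` use 50 subjects /
2 groups / 100 repetitions, 200 / 3 / 50 and 500 / 4 / 30 — repetition
counts chosen to keep the full study a few seconds of compute while
leaving dozens of resamples per condition, which is ample for consensus
matrices this close to binary. Each condition recomputes everything from
the seed: simulation, FAMD, consensus, Rand index.

## Known limitations

- Gaussian responses only; no concomitant-variable (covariate-dependent
  prior) models.
- No automatic smoothing-parameter selection; `penalty_weight` is manual.
- EM finds local optima; inside consensus runs a single random start per
  run is deliberate (disagreement between runs is signal for the
  consensus matrix), but standalone fits should keep `n_init ≥ 5`.
- The delta-area convention and the 70%-inertia default are conventions,
  stated here so runs are comparable, not claims of optimality.
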