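# Methods

`panelnet` implements the standard two-wave psychometric network workflow:
contemporaneous Gaussian graphical models (GGMs) per wave, a cross-lagged
panel network (CLPN) between waves, centrality indices for both, and
bootstrap accuracy/stability diagnostics — together with a fully specified
synthetic panel generator so every stage can be validated against known
ground truth.

## Data model and preprocessing

The unit of observation is a mother–adolescent dyad measured at two waves
(T1, T2) 18 months apart. Nine scale variables form two constructs: five
maternal parenting practices (warmth, monitoring, inductive reasoning,
hostility, harshness — mother-reported) and four adolescent mental-health
problems (anxiety, depression, aggression, conduct problems —
self-reported). Each scale aggregates multi-item Likert responses.

* **Scoring.** A scale score is the *mean* of its keyed items
  (reverse-keyed item `x` on range `(lo, hi)` contributes `lo + hi − x`).
  The mean keeps the Likert metric and tolerates differing item counts;
  sum-scoring is available as a config option. A score is computed from the
  available items when at least 75% of the scale's items were answered,
  otherwise missing (both the rule and the threshold are configurable).
* **Reliability screening.** Cronbach's alpha
  `α = k/(k−1)·(1 − Σ var_i / var_total)` is computed per scale and wave on
  complete item rows, after reverse-keying. A scale is excluded only when
  `α < 0.60` at *both* waves — a scale that clears the bar at either
  occasion stays. This mirrors standard practice of dropping only
  persistently unreliable instruments.
* **Descriptives.** Skewness is the adjusted Fisher–Pearson coefficient
  and kurtosis the small-sample-corrected excess kurtosis — the conventions
  of the common commercial statistics packages, so the descriptives table is
  comparable with the descriptive tables of published reports.
* **Residualization.** Every retained score column is replaced by its OLS
  residual on an intercept plus encoded covariates (adolescent gender as a
  0/1 indicator, age in years, maternal education and family income as
  integer ordinal codes). Networks estimated on residuals therefore reflect
  covariate-adjusted associations. Degenerate (constant/collinear)
  covariate columns are dropped with a warning. Missing-data handling is
  listwise deletion over the 18 score columns plus covariates — the simplest
  defensible default for a low-missingness panel.

## Contemporaneous networks (GGM)

Edges are partial correlations `ρ_ij = −Θ_ij / √(Θ_ii Θ_jj)` from a sparse
precision matrix `Θ` estimated by the graphical lasso:
maximize `log det Θ − tr(SΘ) − λ Σ_{i≠j}|Θ_ij|` over positive-definite `Θ`,
with `S` the Pearson correlation matrix of the residualized scores
(a Spearman-to-Pearson rank transform is available for raw ordinal input).

* **Penalty selection.** 100 log-spaced λ values from `λ_max` (the smallest
  λ giving an empty graph, `max_{i≠j}|S_ij|`) down to `0.01·λ_max`; the
  selected model minimizes the Extended BIC
  `EBIC = −2ℓ + E·log n + 4·E·γ·log p` with `ℓ = (n/2)(log det Θ − tr(SΘ))`,
  `E` the edge count and `γ = 0.5` (the conventional default for
  psychological networks; `γ = 0` is plain BIC). EBIC ties break toward the
  larger (sparser) penalty.
* **Solver.** Block coordinate descent with lasso sub-problems
  (scikit-learn's graphical lasso), duality-gap tolerance `1e-5`, iteration
  cap 500, inner lasso tolerance matched to the outer one. A residual gap
  slightly above tolerance at the small-λ end of a path is tolerated (it is
  orders of magnitude below edge sampling noise); a persistently large gap
  raises a convergence error. Entries shrunk to zero are stored as exact
  zeros.
* **Known behavior.** With strong true edges, EBIC prefers a small λ (less
  L1 bias on the big edges) and consequently admits a few *tiny* spurious
  edges — magnitudes an order of magnitude below the true ones. This is a
  documented property of EBIC-tuned graphical lasso, not an implementation
  artifact; the recovery tests assert exactly this profile.
* **Reporting.** The cross-wave edge table averages T1 and T2 weights per
  pair, rounding half-away-from-zero to 2 decimals (0.445 → 0.45); pairs
  are shown when the absolute weight exceeds 0.01 at either wave (an
  average-based filter is available).

## Temporal network (CLPN)

Each T2 variable is regressed on *all nine* T1 variables with an L1
penalty: minimize `(1/2n)‖y − Xβ − β₀‖² + λ‖β‖₁` (intercept unpenalized).
The directed matrix `d[i, j]` holds the coefficient of T1 node `i`
predicting T2 node `j`; diagonal entries are autoregressive paths, which are
reported but excluded from temporal-network figures and centralities
because they dominate every cross-lagged path.

* Predictors are standardized internally; coefficients are reported on the
  original predictor scale (unstandardized).
* Each outcome node gets its own λ, chosen to minimize mean out-of-fold
  squared error over a 100-point log-spaced grid
  (`λ_max` down to `10⁻³·λ_max`) under 10-fold cross-validation with one
  seeded fold assignment shared across the nine node-wise fits. The
  *minimum*-CV rule (not 1-SE) is used deliberately: the method's purpose is
  to report many small directed edges (down to ±0.01), which a 1-SE rule
  would erase. The cost is a known tolerance for spurious tiny edges under
  the null (~20% of null coefficients nonzero but negligible in magnitude at
  n = 2000); the recovery tests assert that true edges are always found and
  always dominate the spurious ones.
* The reporting view keeps off-diagonal edges with `|d| > 0.01`, sorted by
  descending weight, rounded half-away-from-zero.

## Centrality

* **Expected influence (EI)**, contemporaneous: `EI(i) = Σ_{j≠i} w_ij` —
  a *signed* sum, so negative edges pull a node's influence down (unlike
  strength, which sums `|w|`). One-step EI only.
* **In/out-prediction**, temporal: signed sums of permitted incoming
  (column) or outgoing (row) entries of `d`. The `cross_lagged` variant
  excludes only the node's autoregressive path; `cross_construct`
  additionally excludes edges within the node's own construct, isolating
  parenting → mental-health (and reverse) influence.
* **Variance-explained in-prediction** is provided as a separately labeled
  index: the squared correlation between a T2 node and its fitted linear
  predictor restricted to permitted T1 predictors (non-permitted
  coefficients zeroed). It is bounded by the unrestricted OLS R² and equals
  `β²·var(x)/var(y)` in the single-predictor case. Both readings of
  in-prediction (edge sum vs variance share) are exported with an explicit
  label; neither is silently preferred.

## Bootstrap accuracy and stability

All stochastic stages derive replicate seeds deterministically from a
mandatory master seed, so serial and parallel execution agree and a rerun is
bit-identical.

* **Edge accuracy:** nonparametric bootstrap (resample n rows with
  replacement, refit the full estimator, 2.5/97.5 percentile intervals);
  default 1000 replicates. Replicate fit failures are logged and skipped;
  more than 5% failing is an error. Percentile (not BCa) intervals, recorded
  in metadata.
* **Centrality stability:** case-drop bootstrap. For each drop proportion
  q in {10%, …, 70%, 75%}, subsample `(1−q)·n` rows without replacement
  (default 250 times), recompute centralities, and correlate with the
  full-sample centralities. The CS coefficient is the largest q such that
  the correlation is ≥ 0.7 with probability ≥ 0.95. The search proceeds from
  small q and stops at the first failing level, making the pass/fail
  decision monotone by construction. A constant centrality vector counts as
  a failed correlation (it carries no ordering information). CS below 0.25
  flags unstable centrality ordering; above 0.50 is comfortable.
* **Difference tests:** two estimands differ when the (α/2, 1−α/2)
  percentile interval of their replicate-wise (paired) differences excludes
  zero; α = 0.05 two-sided by default, flagged in output metadata.

## Synthetic panel generator

The generator is the package's ground-truth instrument; its defaults encode
the study conditions the pipeline is meant to handle.

* **Contemporaneous truth:** a sparse 9×9 partial-correlation matrix with
  positive within-construct blocks (strongest: warmth–inductive reasoning
  0.45, hostility–harshness 0.45, anxiety–depression 0.50,
  aggression–conduct 0.55) and weak negative cross-construct bridges
  (monitoring–conduct −0.10, warmth–hostility −0.08). The implied precision
  matrix is diagonally dominant, hence positive definite; T1 scores are
  multivariate normal with the implied correlation matrix.
* **Temporal truth:** `T2 = T1·B + ε` with autoregressive diagonal 0.5 and
  sparse cross-lagged entries, the strongest being hostility→depression
  0.23, harshness→hostility 0.20, anxiety→depression 0.19. Cross-construct
  edges were chosen with distinct per-node out-prediction sums (hostility
  +0.32, harshness +0.15, warmth −0.14, monitoring −0.12, …) so that rank
  recovery of cross-construct out-prediction is a meaningful test rather
  than a test of tie-breaking among zeros; signs follow the plausible
  substantive pattern (negative parenting predicts more problems, warmth
  fewer). Spectral radius of B ≈ 0.7 < 1 (stable). Innovation SDs keep T2
  variances near 1.
* **Covariates:** gender ~ Bernoulli(0.5), age ~ Uniform(8, 17), education
  and income as 4-level ordinals with realistic band probabilities;
  additive effects on scores (e.g. +0.04 SD per year of age on depression)
  make residualization consequential in every test.
* **Measurement:** each scale's items follow a one-factor equi-correlation
  model with the inter-item correlation set by the Spearman–Brown relation
  `r̄ = α/(k − α(k−1))` to hit that scale/wave's target alpha. Targets are
  per-wave and span the published range (0.59–0.88), with harshness at
  (0.59, 0.67) so the both-waves exclusion rule is exercised realistically
  (harshness retained). In Likert mode items are discretized by equiprobable
  normal thresholds, and the latent inter-item correlation is first inflated
  by the classical coarse-categorization attenuation factor
  `c = (Σ φ(τ))²/Var(category score)` so the *observed* responses hit the
  target alpha — published reliabilities describe observed Likert items. A
  skewed-threshold option (geometric category masses) mimics heavily skewed
  scales such as conduct problems.
* **Default n = 591** dyads, mirroring a realistic retained two-wave
  cohort of this design; recovery and calibration tests use larger n
  (5 000–100 000) where statistical consistency, not cohort mimicry, is the
  property under test.

**What the generator does not emulate:** informative attrition, item-level
missingness mechanisms, measurement non-invariance across waves, reporter
effects (all parenting scales share one reporter), and non-normal latent
distributions. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to these real-data
complications.

## Numerical choices and edge cases

* Reporting rounds half away from zero via decimal arithmetic (binary
  floats round 0.445 wrongly under naive multiplication).
* `λ = 0` in either penalized estimator falls back to the exact unpenalized
  solution (matrix inversion / OLS).
* Zero-variance columns raise named errors in correlation and
  standardization steps; constant covariates are dropped with warnings.
* Layouts use Fruchterman–Reingold on the element-wise mean of the two
  absolute weight matrices, seeded and normalized to the unit square, so
  both contemporaneous networks share node positions.
* Fewer than 2·folds observations triggers a leave-one-out CV fallback
  with a warning; fewer than 25 rows after a 75% case drop is a
  configuration error.

## Simulation sizes

The validation suite balances statistical resolution against runtime on a
single CPU: 25 replicates at n = 5 000 for edge/rank recovery, n = 100 000
for moment and reliability calibration, 200 outer simulations at 200
bootstrap replicates for interval coverage and test size, 40 case-drop
replicates per drop level at a 15-point λ path for CS behavior, and reduced
bootstrap counts in the end-to-end determinism runs. These sizes are the
package's chosen operating points for its own validation; production runs
default to the conventional 1000/250 bootstrap replicates.

## Known limitations

* Exactly two waves; no continuous-time or multi-wave dynamics.
* No latent-variable CLPN (observed scale scores only), no mixed graphical
  models, moderated networks, or Bayesian GGMs.
* Bridge/strength/closeness/betweenness centralities are out of scope by
  design (EI and in/out-prediction are the indices of record here).
* The difference test is a percentile bootstrap test; its size is
  approximate (validated at ~5–7% empirically at n = 300).
* Published per-wave tables round to 2 decimals, so a cross-wave average
  recomputed from printed values can differ from a published average
  computed on unrounded weights in the last digit; the package keeps
  unrounded columns alongside rounded ones for this reason.
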