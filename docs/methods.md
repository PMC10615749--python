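# Methods

This note documents the statistical content of `termref`: the models it
fits, the conventions it adopts where published practice is ambiguous,
what the synthetic-data generator does and does not emulate, and the
numerical choices inside the estimators.

## Reference-sample norms and severity bands

For each Bayley-III composite (cognitive, language, motor; valid range
40–160) the reference-sample norms are the sample mean and the sample SD
with the n−1 denominator, computed after dropping missing scores and
requiring at least two observed values. A sample with zero spread is
rejected (`DegenerateVarianceError`) because severity bands would be
undefined.

The SD's sampling uncertainty is summarised with the exact chi-square
interval, `[s·√((n−1)/χ²_{1−α/2}), s·√((n−1)/χ²_{α/2})]` on n−1 degrees
of freedom. The interval assumes normally distributed scores; composite
scores are integer-valued and mildly discrete, which at reference-sample
sizes in the hundreds is immaterial. We chose the exact interval over
large-sample (delta-method) alternatives because it is the standard
textbook interval for a normal SD and reproduces reported intervals in
this literature at one decimal when fed unrounded moments.

Severity cut-points: reference bands sit at mean − 1·SD (moderate) and
mean − 2·SD (severe); manual bands are the publisher's fixed 85/70,
which are exactly the 1/2-SD cuts of the normative N(100, 15). Cuts are
carried at full floating precision and only rounded for display
(half-up; one decimal for moments and CIs, two decimals for cuts,
matching how such tables are printed). Classification is boundary-
inclusive on the healthy side: a score exactly at the moderate cut is
normal/mild, exactly at the severe cut is moderate. Severity is
unbounded below — published three-band listings sometimes print a floor
near mean − 3·SD for the severe band, but no floor is defined
substantively, so we treat the printed lower limit as descriptive.

A child's overall level is the worst level across their non-missing
composites (worst-available rule). Children with no observed composite
are excluded from overall denominators; per-composite denominators
count children observed on that composite. Percent displays round
half-up to whole percents. Demographic comparison tables follow the
same convention, and percentage-point differences are taken between the
*rounded* shares (round-then-subtract) because that is how printed
reports state their deltas; the subtract-then-round alternative — which
can differ by one point — is available behind a flag.

## Clustered comparison models

Each child is classified under both band sources, producing two rows in
long format with an indicator (0 = manual, 1 = reference). The contrast
is estimated conditionally on center:

* binary moderate/severe: logistic regression with fixed effects
  (intercept, band source, optional covariates such as maternal
  education, home language, age at assessment) and a normal random
  intercept per center, `b_c ~ N(0, σ²_c)`;
* three ordered levels: proportional-odds cumulative logit
  `P(Y ≤ k) = expit(c_{k+1} − xβ − b_c)` with ordered thresholds kept
  monotone through a log-gap parameterization, the same random
  intercept, and a common band-source odds ratio.

The marginal likelihood integrates `b_c` by adaptive Gauss–Hermite
quadrature: per cluster, the conditional mode is found by a
safeguarded 1-D Newton iteration (the integrand is log-concave), the
quadrature rule is re-centred at the mode and re-scaled by the Laplace
curvature, and the node sum is accumulated with log-sum-exp. Default 21
nodes; on converged fits, moving from 11 to 41 nodes changes the
maximized log-likelihood by < 1e-6. Rows with identical design values
within a cluster are collapsed to weighted cells, so likelihood
evaluations cost O(cells × nodes) rather than O(children × nodes).

Outer maximization uses L-BFGS-B on (β, thresholds, σ) with σ bounded
at 0 and 3-point finite-difference gradients (ftol 1e-14, gtol 1e-9 —
tight enough that the two-category ordinal fit and the binomial fit,
which share one likelihood surface under c₁ = −β₀, agree to ~1e-9).
Standard errors come from the inverse observed information (numerical
Hessian; pseudo-inverse fallback when σ̂ sits on the zero boundary).
Degenerate cases: σ²_c = 0 reduces exactly to ordinary logistic /
proportional-odds regression; an outcome without variation and a fixed
effect diverging beyond |15| on the log-odds scale (separation) raise
estimation errors.

The reported OR is *conditional* (center-specific); with σ²_c > 0 it
exceeds the population-averaged 2×2 OR in magnitude, which is why the
package also exposes the marginal cross-tabulated OR with its Wald CI
as a diagnostic companion. The latent-scale intraclass correlation is
σ²_c/(σ²_c + π²/3).

The two classifications of one child are correlated; published analyses
of this design state clustering by center only, so the default model
does the same. A nested child-within-center random intercept is
available behind `child_intercept=True` (child-level integral by plain
Gauss–Hermite scaled by the child SD inside an adaptive center-level
integral) for sensitivity analysis of that pairing; it is materially
slower and not the default. No multiplicity adjustment is applied —
p-values are reported unadjusted, as is usual for this design's
descriptive contrasts.

The fitter was cross-validated against `lme4::glmer` with the same
quadrature rule (agreement ~1e-6 on coefficients and the variance
component on a 12-center test problem; see the test suite) and, at the
σ = 0 boundary, against `statsmodels` Logit/OrderedModel.

## Design and power arithmetic

The design question is a two-group comparison of impairment proportions
(5% under manual norms vs 15% under reference-derived thresholds, 180
children per group, α = 0.05, two-sided). Neither the test statistic
nor the clustering treatment behind published power figures is ever
fully stated, so the package makes its own choices explicit:

* **Analytic**: normal approximation with pooled-null standard error,
  `power = Φ((d − z·se₀)/se₁) + Φ((−d − z·se₀)/se₁)`; this gives 0.889
  at the design parameters and ≈ α under the null.
* **Simulated**: Monte-Carlo replicates of the pooled-SE two-proportion
  z-test on exact Bernoulli/binomial draws; at the design parameters
  with 5000 replicates this lands at ≈ 0.90–0.91 (the discrete exact
  test sits slightly above the normal approximation), with an exact
  Clopper–Pearson CI on the rejection fraction, and rejection ≈ 0.05
  under the null.
* **Clustering**: children are spread as evenly as possible over
  `n_clusters` centers per group with independent normal random
  intercepts on the logit scale; the intercept variance is
  icc·(π²/3)/(1 − icc) so the *latent* ICC equals the input, and the
  group intercepts are calibrated by quadrature + root-finding so the
  *marginal* rates equal the requested probabilities. Independent (not
  shared) center effects per group are used so the clustering penalty
  behaves like a cluster-randomized contrast: power decreases in ICC,
  consistent with the design effect 1 + (m−1)·ICC.

Sample-size search inverts the monotone analytic power curve by
bisection. Accrual bookkeeping reports round(n_index/n_reference) as
"1:k".

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, with
defaults chosen to mirror a realistic multicenter follow-up study: 15
centers, 97 index (extremely preterm) children per center, reference
accrual at 1:5 (ceil(index/ratio) per center), reference composite
means/SDs of (97.5, 97.9, 98.2)/(11.2, 16.0, 10.9) and index
(83.9, 80.2, 83.3)/(15.1, 17.4, 16.2) for cognitive/language/motor, a
center-membership ICC of 0.05, and per-composite missingness of
(0.5%, 3%, 3.5%) — cognitive nearly always scored, motor most often
missing, at the low single-digit rates typical of completed Bayley
visits. The cross-composite correlation defaults to 0.6, a mid-range
value for Bayley composites at age two; no published value constrains
it, and it does not enter any per-composite acceptance quantity.

Latent scores are `mean + sd ∘ (u_center + e_child)` with
`u_center ~ MVN(0, icc·R)` shared by both cohorts of a center and
`e_child ~ MVN(0, (1−icc)·R)`, R the exchangeable correlation matrix —
so each composite's total variance is sd² with fraction icc between
centers. Scores are rounded half-up to integers (composites are
integer-valued; fractional cut-points like 86.21 are only meaningful
against integer scores), clipped to [40, 160], and then each composite
is independently masked missing-completely-at-random at its configured
rate — no published missingness mechanism exists, so MCAR is the
neutral choice. Eligibility screening of candidate term births applies
the chart-review rules (singleton at 39 0/7–40 6/7 weeks, appropriate
weight, no resuscitation/anomaly/NICU admission, no CNS disorder,
protective-custody or parental exclusion) in listing order and reports
*all* failed criteria, not just the first.

What the generator does **not** emulate: recruitment dynamics and
selection bias of the reference sample (the very phenomenon that makes
real reference samples demographically unrepresentative), covariate-
outcome associations, informative missingness, heavier-than-normal
tails or ceiling/floor clumping of real Bayley scores, and unequal
center sizes unless configured. Passing tests therefore demonstrate
that the *estimators* are correct under the stated model, not that the
model captures every feature of real follow-up data.

## Problem sizes used in the checks

The moment-recovery checks use ~1800 reference children (15 × 600 index
at 1:5) so 3-standard-error bands are tight; ICC recovery uses 100
centers × 100 children, where the one-way ANOVA estimator's Fisher SE
is ≈ 0.008; mixed-model parameter recovery uses 200 cohorts of 15
centers × 100 children at true log OR 0.62 and σ²_c = 0.17 (observed
mean 0.622, Monte-Carlo SE 0.005); power simulations use 5000
replicates. These sizes were chosen so that each check's Monte-Carlo
error is small against the effect it verifies.

## Known limitations

* The mixed models support a single grouping factor (center), plus the
  optional nested child intercept for the binomial model only; crossed
  random effects are out of scope.
* Wald inference throughout; no profile-likelihood or bootstrap CIs,
  which matters mostly when σ̂²_c is near the boundary.
* The proportional-odds assumption is not tested within the package.
* Reference norms are unconditional — no age-stratified or
  regression-based (covariate-adjusted) norming.
* `PowerDesign` treats both groups as the same size; unequal group
  power is available only analytically.
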