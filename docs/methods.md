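# Methods

## Generating model and what the synthetic data emulate

Daily intakes of a daily-consumed nutrient are simulated from a Box-Cox
variance-components model: person means `b_i ~ N(μ, σu²)` on the
transformed scale, `k = 2` daily values `y_ij ~ N(b_i, σε²)`, and the
inverse Box-Cox map `x = (λy + 1)^(1/λ)` back to the original scale.
Defaults are μ = 7.5 and λ = 0.2; the 12 built-in scenarios cross
n ∈ {150, 300, 500} with (σε², σu²) ∈ {(1, 0.25), (1, 0.11), (1.2, 0.3),
(2.7, 0.3)}, i.e. within/between variance ratios of 4 and 9. These are the
study conditions; they produce right-skewed, strictly positive intakes with
analytic original-scale means of 105.5625, 104.6677, 107.1663 and 116.9463
for the four variance families.

The generator emulates the balanced two-replicate design only. Real recall
data additionally have nuisance day effects (weekday, season, interview
mode), covariates, unbalanced replicate counts, episodic (zero-inflated)
foods, and transformed-scale distributions that are only approximately
normal. Passing tests therefore demonstrate correctness of the estimators
*under their own model assumptions* and the comparative behaviour of the
three back-transformation strategies — not robustness to model
misspecification.

Per-person random substreams are keyed by `(seed, person_id)`
(`numpy.random.SeedSequence`), so datasets are reproducible, independent of
iteration order, and the first n persons are unchanged when n grows. A
simulated transformed value with `λy + 1 ≤ 0` (about 7σ from the mean under
the default parameters, so effectively never) is redrawn; more than 1000
redraws in one dataset raises, flagging a pathological parameter choice.

## The estimators

All three share: a Box-Cox transform of the observed intakes, one-way
random-effects variance components, and a back-transformation that
integrates out the within-person noise.

**Variance components** are method-of-moments (balanced one-way ANOVA):
`σ̂ε² = MSW`, `σ̂u² = (MSB − MSW)/k`, truncated at zero. On this balanced
intercept-only design MoM coincides with REML, so one estimator serves all
three methods and keeps them comparable; a raw between-person estimate
below 1e−12 is treated as exactly zero and marks the sample degenerate.

**λ selection.** SPADE- and NCI-style fits use the free profile MLE of the
one-parameter transform on the pooled observations (the marginal of the
generating model is exactly Box-Cox normal, so pooled and mixed-model MLE
agree closely here). The profile log-likelihood, including the Jacobian
term, is `scipy.stats.boxcox_llf`; the search is a bounded scalar
minimization on [0.01, 1] (xatol 1e−5). The lower bound stays strictly
positive so the optimizer never crosses the λ = 0 branch; the log transform
is available explicitly as λ = 0. The MSM-style fit restricts λ to
{1/d : d = 1..10} (covering λ ≥ 0.1) and adds a shift `−min + 1e−6·range`
only when values are non-positive.

**Back-transformations.** The quadrature form is
`BT(t) = Σ w_m g⁻¹(t + √2·σε·x_m)/√π` over Gauss–Hermite nodes; the
out-of-domain branch of g⁻¹ is clamped to 0, which is what makes the far
lower tail integrable. SPADE-style estimates use 60 nodes by default
(exactness at λ = 0.2 needs only 3; other λ are genuinely approximate);
the NCI-style back-transform is fixed at 9 nodes — exact through
polynomial degree 17. The MSM closed form expands
`E[(λ(t + ε) + 1)^r]` binomially for λ = 1/r, keeping only even normal
moments; it equals the quadrature value to rounding for integral 1/λ, and
results are floored at 0 (intakes are non-negative).

**NCI pseudo-persons.** k = 50 000 by default: the Monte-Carlo error of the
empirical percentiles is then well below the estimator-bias signal at
negligible cost. Empirical quantiles interpolate order statistics linearly
at position p(k − 1) + 1 (numpy's default), chosen once and documented so
runs are bit-reproducible.

**MSM shrinkage.** The first stage is an intercept-only regression (no
covariates appear in any scenario), so the working values equal the
observations; the fitted-value plumbing is kept so a covariate stage can
slot in later. Each person's transformed mean is pulled toward the grand
mean by `σ̂u²/(σ̂u² + σ̂ε²/k)` — the best linear predictor of the person
effect. The estimated distribution is the empirical distribution of the n
back-transformed shrunken means; being a distribution of predictors, its
variance is smaller than σu² by the same reliability factor, so this
estimator is intrinsically narrower than the other two, most visibly in
the outer percentiles at high variance ratios.

## The evaluation harness

Each replicate generates one sample and runs all three estimators. A
sample whose between-person variance is estimated as zero by any method
(or where any estimator fails outright) is excluded for all methods —
mirroring how unusable runs are handled when comparing software that stops
on a zero variance. Summaries are produced both with and without the
exclusion rule. Bias, relative bias (|B/θ|·100) and MSE are computed per
method × statistic over usable replicates against the quadrature oracle;
Bonferroni t intervals use family size 3 (the methods compared within one
scenario-statistic panel) — the family is a config knob since other
choices (e.g. methods × percentiles) are defensible.

Seeding is hierarchical: study seed → per-(scenario, replicate) substream
→ per-person substream, with the NCI pseudo-person draw on its own
substream so method order can never affect the data. Substream seeds are
derived through `SeedSequence` and kept below 2³¹.

The default replicate count is 1000; the acceptance-style tests run
scenario batches at 200–500 replicates, which resolves the directional
bias phenomena (P10 overestimated, P90 underestimated; exclusions more
frequent at variance ratio 9 and n = 150) while keeping a full suite run
in the minutes range.

## Numerical choices and degenerate inputs

- Transform round-trip: `g⁻¹(g(x)) = x` on the valid domain for all
  λ ∈ [0, 1], shift ≥ 0; the inverse is non-decreasing with equality only
  on the clamped region.
- Percentile maps returned by estimators and the oracle are made
  non-decreasing by a cumulative-max pass; this only ever repairs sub-ulp
  rounding inversions in otherwise monotone quantile computations.
- A degenerate sample (σ̂u² = 0) yields all percentiles equal for every
  method: SPADE/NCI collapse to the back-transformed mean, MSM shrinks
  every person fully to the grand mean.
- Datasets must be balanced with k ≥ 2 days and n ≥ 2 persons; unbalanced
  input raises rather than silently reweighting.

## Known limitations

- The distribution of BLUP-shrunken means (MSM-style) understates the
  between-person spread by construction; no re-inflation step is applied
  because the method is implemented as specified.
- The free-λ MLE is weakly identified when the coefficient of variation of
  the data is very small (the transform family is then nearly
  scale-equivalent); this does not arise under the built-in scenarios.
- Only daily-consumed (never-zero) intakes are covered; episodic foods,
  covariates, survey weights and unbalanced designs are out of scope.
- The grafted-polynomial normality transform used by a fourth family of
  estimators is not implemented; its moment-based variance-component idea
  is what the shared ANOVA estimator retains.
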