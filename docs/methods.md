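# Methods

## The measurement problem

Given individual survey records of women with a recent birth — a continuous
asset-based wealth index, a sampling weight from a two-stage cluster design,
demographic covariates, and maternal-health outcomes (antenatal-care visit
counts, completeness of the four recommended postnatal reviews, facility
delivery) — the package quantifies how strongly utilization of each service
is concentrated among richer or poorer women, how that concentration changes
between two survey rounds, and how much of it survives adjustment for
non-wealth demographics.

## Fractional rank and the concentration index

Records are sorted by wealth score; with normalized weights `w_i` the
fractional rank is the weighted mid-rank

    r_i = sum_{j<i} w_j + w_i / 2  ∈ (0, 1),

with tied scores receiving the weighted average of their block's mid-ranks
(this makes every estimator invariant to the ordering of tied records).  For
an outcome `h` with weighted mean `mu > 0`, the concentration index is

    CI = (2 / mu) * sum_i w_i h_i (r_i - rbar),

positive when the outcome is concentrated among the rich.  Three routes are
implemented and cross-checked:

* **covariance formula** — the expression above; the algebraic oracle.
* **convenient regression** — WLS of `2·var_w(r)·h_i/mu` on `r_i` with
  weights `w_i`.  The slope equals the covariance formula identically (not
  just asymptotically); the conventional WLS slope standard error is the
  default inference route, with an HC0 sandwich option.  Robustness is not
  the default because the simplest reading of the estimator is the plain
  regression error; the flag exposes the alternative.
* **area** — `1 − 2·(trapezoid area under the concentration curve)`.  At the
  individual level this agrees with the covariance formula to O(1/n)
  (empirically far better); on the 6-point quintile curve it is the value a
  reader would obtain from a published quintile table.

Curves are cumulative outcome share against cumulative population share,
poorest to richest; quintile grouping interpolates the individual-level
curve at population shares 0.2, …, 0.8.  Curve dominance is classified by
comparing ordinates on the union of the two abscissa grids with tolerance
1e-9: `cross` when the sign of the difference changes, dominance when one
curve is weakly above everywhere and strictly somewhere.

## Recoded analysis variables

* ANC: `none` (0 visits), `up_to_four` (1–4), `more_than_four` (≥5).  The
  boundary placement of exactly four visits is genuinely ambiguous between a
  literal "more than four" reading and the WHO "four or more" adequacy
  convention; the literal reading is the default and `anc_four_in_upper=True`
  switches to the WHO convention.
* PNC: `complete` iff all four review components (post-delivery,
  pre-discharge, week after, six weeks) are present; any miss is
  `incomplete`.
* Wealth quintiles: records sorted by score and cut at cumulative normalized
  weight 0.2/0.4/0.6/0.8.  A tied block is assigned as one unit to the
  quintile containing the midpoint of its cumulative-weight span — the
  weight-balanced, order-independent rule; for untied records this midpoint
  is exactly the fractional rank.  An all-tied input degenerates to a single
  quintile with a warning rather than an error.

## Covariate standardization

A weighted prediction model regresses the outcome on wealth terms plus
controls (education, occupation, residence, ethnicity, religion, age band,
number of children).  Wealth enters as quintile indicators by default; the
continuous score and the fractional rank are selectable because nothing in
the method forces one choice.  The default link is identity (the convenient-
regression framework is linear); logit and log links are available.

Each record is re-predicted with its own wealth terms and all controls
frozen at their weighted means; the adjusted CI is the CI of those
predictions.  This is a *partial* (direct) standardization of the
wealth–outcome gradient; classical indirect standardization
(`h_i − ĥ_i + h̄`) is provided as `mode="indirect"`.  Identity-link
predictions can be negative; they are reported as-is, and an adjusted mean
that is not positive raises rather than being silently repaired.

For the standard error the regression is rerun with the outcome left
untransformed and the rank rescaled instead:

    RWealth_i = (mu / (2·var_w(r))) · r_i,

so that the slope of `adjusted_h ~ RWealth` *is* the CI and its conventional
slope standard error is reported directly.  The scaling is the inverse of
the outcome transform of the convenient regression — the only choice for
which the slope reproduces the covariance-formula value (property-tested to
1e-10).  The rank variance depends only on the weights and is treated as a
constant in this calculation.  The adjusted standard errors are much smaller
than unadjusted ones because the standardized outcome is a smooth function
of the wealth terms with the covariate noise removed; the same pattern
appears in published applications of this estimator.

## Between-survey inference

Two indices with standard errors are compared with
`z = |CI_a − CI_b| / sqrt(SE_a² + SE_b²)` against the standard normal,
two-sided by default.  Rich–poor odds ratios from two rounds are compared
with the same statistic *on the odds-ratio scale* (standard errors given on
that scale), one-sided upper-tail by default: the published worked examples
this package reproduces are only consistent with that convention (their
printed SEs combine to the printed statistic only without a log transform,
and the printed p-value equals the one-sided tail of the statistic).  A
log-scale variant with delta-method SEs is available; the two disagree
noticeably when the ORs are far from 1, and the log scale is the better
default for new analyses — the raw scale is kept as default for fidelity.

Institutional delivery is modelled by weighted binary logistic regression:
one single-covariate model per covariate (unadjusted) or all jointly
(adjusted), survey weights applied as frequency weights normalized to sum to
n, normal-approximation 95% intervals, Wald p-values.  Variance is
design-effect-free by default (sandwich errors behind a flag); cluster-level
jackknife variance is out of scope.  Separation and degenerate fits raise
errors naming the offending terms.

## The synthetic survey generator

The generator emulates a national DHS round, not any real dataset:

* **Design** — 353 EAs of nominally 85 listed households (actual listing
  varies uniformly ±25), 22 sampled per EA, one respondent per household.
  EAs are drawn PPS within urban/rural strata with urban strata oversampled
  (factor 1.6); weights are products of the two inverse selection
  probabilities, normalized to mean 1.  Per-cluster RNG substreams are
  spawned from the root seed, so cluster c's records do not change when
  `n_clusters` changes.
* **Wealth** — standard log-normal score with a cluster-level random effect
  (SD 0.3 on the log scale) plus an additive urban shift (+1.5).  Only the
  rank ordering matters for every downstream estimator, so the family is a
  labelled stand-in.
* **Covariates** — drawn per configured level prevalences (defaults: ~70%
  no education, ~70% rural, ~80% Muslim, seven 5-year age bands, sibling
  groups mapped to a child count).  Prevalences are validated to sum to 1.
* **Outcomes** — ANC counts are Poisson with
  `log E[h] = log(baseline) + g_anc·(r − 0.5) + effects`; each of the four
  PNC components and facility delivery are Bernoulli with the analogous
  logit predictors.  `baseline_rates` are reference-profile levels at
  mid-rank (ANC mean 4.2 visits; PNC per-component 0.55, giving ~9%
  completeness; delivery 0.27), chosen to resemble a pre-intervention
  West-African survey round.  Default covariate effects make education and
  urban residence raise utilization; because residence correlates with
  wealth, this builds genuine confounding into the default conditions, which
  is what the standardization stage is for.  Consequently a zero *direct*
  gradient does not give a zero CI under the defaults; the null-CI property
  holds when the covariate effects are switched off, and tests state it that
  way.

`calibrate_gradient_to_ci` finds the gradient reaching a target CI by
bisection on [−6, 6], evaluating the covariance-formula CI on a population
generated with a fixed seed (a deterministic objective), default tolerance
0.002 on the fixed sample; fresh-sample recovery is then limited by Monte
Carlo noise (~0.003 for the ANC count at n ≈ 50 000).  Unreachable targets
raise with the achievable range.

What the generator does **not** emulate: asset-index construction by PCA,
non-response, within-household selection of multiple eligible women,
spatial/regional structure, or overdispersion beyond Poisson.  Passing tests
therefore show correctness of the estimators and calibration machinery under
a clean two-stage design, not robustness to every feature of real DHS data.

## Verification design

* Worked examples: published estimate/SE pairs are fed through the test
  machinery and must reproduce the published statistics (10.78, 6.70, 4.84;
  1.80 with one-sided p ≈ 0.0359) and the published 95% bounds of the
  adjusted indices to printed precision.
* Oracle equivalence: 200 random weighted datasets (n ≤ 500); convenient
  regression must match the covariance formula within 1e-10 and the
  individual-level area estimate within 2/n.
* Parameter recovery: gradients calibrated to CI targets {−0.05, 0, +0.10}
  for the ANC count outcome (the count outcome is the calibration example
  of record and has the smallest Monte-Carlo error) must be recovered within
  ±0.01 on a fresh ~50 000-record round; a unit wealth-rank log-odds effect
  on delivery must be recovered within 3 SE at n ≈ 5 000 via the
  continuous-rank logistic fit.
* Type-I error: 1 000 pairs of disjoint 500-record subsamples from one
  null population (no wealth channel); the difference-in-CI test must reject
  at 0.05 ± 0.02.  This checks the conventional slope SE end to end.

Problem sizes (50 006 records for calibration, 909 clusters for the null
population, 1 000 replicates) were chosen so the full suite runs in well
under a minute per stochastic block while keeping Monte-Carlo margins
comfortably inside the stated tolerances.

## Known limitations

* The convenient-regression SE ignores the sampling variability of `mu` and
  of the ranks; fine at the null and for small indices, optimistic for large
  ones.
* No Erreygers/Wagstaff normalization: for bounded outcomes (PNC
  completeness, delivery) the plain CI's attainable range shrinks with the
  mean, which matters when comparing rounds with very different coverage.
* Weighted logistic variance treats weights as frequencies; design-based
  (jackknife) variance would be wider.
* Dominance classification is descriptive (tolerance-based), not a
  statistical test.
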