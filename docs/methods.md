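# Methods

This note documents the statistical model, the numerical choices and the
limits of what the synthetic-cohort validation can show.

## Indirect reference-interval estimation

Routine results of an analyte in one trimester stratum are modelled as a
finite mixture of a dominant non-pathologic (healthy) component and optional
pathologic contamination components. The healthy family is chosen by the
analyte's shape: Gamma(shape k, rate r) for TSH, whose distribution is
strongly right-skewed and strictly positive, and Normal(μ, σ) for FT4, which
is approximately symmetric. Contamination components share the healthy
component's family and are seeded below and above the main mode; their role
is to absorb pathologic mass, not to be interpreted.

The reference interval is the healthy component's parametric central range:
its inverse-CDF quantiles at (1−coverage)/2 and 1−(1−coverage)/2, coverage
0.95 by default. Parametric quantiles (rather than empirical percentiles of
trimmed data) follow directly from the mixture decomposition and are smooth
at the tails. Display rounding is two decimals for TSH and one for FT4;
comparisons are computed at full precision.

### Initialization

A Gaussian-kernel density estimate (Silverman bandwidth h, 512-point grid
spanning the data ± 3h) locates the dominant mode. The healthy component is
centred there, with spread taken from the sample interquartile range
(IQR/1.349, the normal-consistent robust scale); for the gamma the (mode,
spread) pair is converted through the mode relation (k−1)/r, falling back to
moment matching when the mode conversion is infeasible. Pathologic
components start at the 1st and 99th sample percentiles with coefficient of
variation 1 (gamma) or the healthy spread (normal). The healthy starting
weight is the assumed healthy:pathologic ratio, default 0.90; the fit is
insensitive to this choice (the suite verifies limits move < 1% across
starting ratios 0.80–0.95), so it does not need to be chosen accurately.

### EM and the weighted MLEs

Standard EM: E-step responsibilities from log densities with log-sum-exp
renormalisation; M-step weight updates are mean responsibilities, and
component parameters come from weighted maximum likelihood:

* normal — weighted mean and ML (denominator Σw) standard deviation;
* gamma — Newton iteration on the profile score ln k − ψ(k) = ln Ā − L̄
  (Ā weighted arithmetic mean, L̄ weighted mean log) from the closed-form
  starting value k₀ = (3 − c + √((c−3)² + 24c))/(12c), c = ln Ā − L̄, with a
  Brent bisection fallback if a Newton step leaves (0, 10⁶); tolerance 1e-10
  on the score; rate r = k/Ā. Numerically constant data (c → 0) cap the
  shape at 10⁶ with a warning.

Convergence: relative log-likelihood improvement below 1e-8, or 2000
iterations. Components whose weight falls below 1e-4, or whose spread
degenerates, are pruned (weights renormalised) and fitting continues; the
recorded likelihood trace covers contiguous iterations on one component set
and is non-decreasing up to 1e-9 relative floating error. If the nominal
healthy component ends up lighter than a contamination component, the
largest-weight component is re-identified as healthy with a warning — on
realistic contamination fractions this does not occur.

Fitting uses the raw values, not binned counts. At the sample sizes involved
(thousands and above) the binned multinomial likelihood and the raw-value
likelihood give coinciding estimates; `histogram_loglik` provides a
Freedman–Diaconis binned-likelihood cross-check used in the tests.

### Main-part diagnostic and model selection

The healthy-population assumption concerns the main part of the data,
operationalised as the healthy component's central 90% (5th–95th
percentile; configurable). The goodness-of-fit score is the
Kolmogorov–Smirnov sup-distance between the fitted full-mixture CDF and the
empirical CDF restricted to that region.

Candidate models (per family: healthy-only, and healthy + low/high
contamination) are compared on this score. Selection is by minimum KS with a
parsimony band: candidates within 1/√n of the best score are statistically
indistinguishable, and among them the fewest components win, then the higher
log-likelihood. The band's scale is principled: the KS distance of a
correctly specified *fitted* model concentrates at order n^(−1/2), and a
flexible over-parameterised mixture can absorb exactly that much empirical-
CDF sampling noise. Without the band, contamination components fitted to
pure healthy data siphon a few percent of tail mass and bias the healthy
quantiles; with it, contamination is retained only when it displaces the
main-part CDF beyond noise — which 5–10% planted contamination does by an
order of magnitude.

A consequence worth knowing: contamination that is symmetric and heavily
overlapping (the FT4 default, ±3 pmol/L ≈ 1.4 σ shifts at 5% each side) may
be statistically indistinguishable from a slightly wider single normal in
the main part. The selection then keeps the single-component fit, widening
the limits by a few percent of their value — the validation suite bounds
this at under 5% relative error under the default contamination conditions.

## Cleaning cascade

Seven exclusion criteria applied in fixed order, each record attributed to
the first criterion it violates so the funnel reconciles exactly: missing
values (any analyte or the patient identifier), missing age, non-female sex,
age outside 20–45 (inclusive bounds retained; non-integer ages floored),
multiple records per patient during the period (all of that patient's rows
dropped; multiplicity is counted over the whole input), analyte outside the
analytical measurement range (TSH [0.005, 100.00] mIU/L, FT4 [0.3, 100]
pmol/L; strict exclusion — a value exactly at a bound is retained), and
TPO-Ab strictly above 34 IU/ml. Records whose gestational week is missing
or below 4 cannot be assigned a trimester and are excluded separately from
the seven criteria. Trimesters are weeks 4–12 / 13–27 / ≥28; age bands the
five closed intervals 20–25 … 41–45.

## Synthetic-cohort generator

The generator is the validation instrument: it produces cohorts whose
healthy laws, contamination fractions and dirty-record counts are known
exactly.

* **Healthy laws.** Per trimester, TSH gamma and FT4 normal parameters are
  calibrated deterministically (2-D root find on the gamma CDF; closed form
  for the normal) so the central 95% range equals published
  trimester-specific limits for a Roche-platform pregnant population
  (TSH 0.40–4.09 / 0.57–4.04 / 0.73–4.07 mIU/L; FT4 12.2–20.5 / 10.2–18.2 /
  9.0–15.5 pmol/L). A two-parameter family pinned to two tail quantiles has
  no freedom left for the median; the implied first-trimester TSH median is
  1.58 mIU/L and the FT4 mean 16.35 pmol/L, close to but not exactly the
  published medians (1.59, 16.00) — the tails, which define the interval,
  take priority.
* **Covariates.** Maternal ages are drawn over the five bands with
  proportions 22/44/23/9/2%, mimicking a large obstetric laboratory's age
  structure; FT4 carries a small negative age slope (−0.05 pmol/L per year
  about the reference age of 28), matching the published band-to-band
  decline of roughly 1 pmol/L over 20 years. Gestational weeks are uniform
  within each trimester's span.
* **Contamination.** Hypothyroid records multiply TSH by 4 and shift FT4
  down 3 pmol/L; hyperthyroid records multiply TSH by 0.05 and shift FT4 up
  3 pmol/L — multiplicative on the log-scale-natural TSH, additive on FT4,
  sized to overlap the healthy bulk rather than separate cleanly.
  TPO-Ab-positive records draw TPO-Ab above the cutoff and elevate TSH by
  ×1.5. Default fractions are 5% each.
* **Dirty records.** Each cleaning trigger (missing value, male sex, age
  out of range, duplicate patient pair, out-of-AMR value, TPO-Ab above
  cutoff) is planted disjointly at 1% by default, on otherwise-healthy
  records, so per-criterion exclusion counts are exactly predictable.
* **Determinism.** One master seed; each trimester uses a derived substream,
  so regeneration is bit-identical and stratum sizes can change without
  perturbing other strata.

What the generator does **not** emulate: assay measurement error and batch
effects, calendar-time drift, within-pregnancy repeat testing, iodine-status
heterogeneity, or continuous gestational-week trends within a trimester.
Passing recovery tests therefore show the estimator handles the mixture
structure, not that real-world records satisfy the mixture assumptions.

## Validation problem sizes

The suite exercises coverage calibration on an uncontaminated cohort of
50 000 (the estimated interval's empirical coverage matches 95% within three
binomial standard errors), healthy-limit recovery under 10% contamination at
n = 30 000 (within 5% relative error for both families), EM optimality
against a 10⁴-point grid-search oracle at n = 200, and exact funnel
reconciliation on planted triggers. These sizes make the Monte-Carlo noise
small relative to the tolerances while keeping the full suite to a few
minutes.

## Known limitations

* Trimester strata are treated as homogeneous; continuous gestational-age
  reference curves are out of scope.
* The pathologic components' distributional forms are modelling conventions,
  not estimates of disease biology; only the healthy component is
  interpreted.
* Age-band-specific intervals are reported from empirical percentiles per
  band (a mixture fit per band would need the band's own sample size to be
  large); the all-ages row carries the fitted parametric limits.
* The chi-square comparison of abnormal rates treats the two classifications
  of the same subjects as independent samples, following the conventional
  presentation; a paired McNemar variant is available behind a flag.
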