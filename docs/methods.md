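# Methods

## Setting and model

The package analyses two-sample summarized Mendelian randomization (MR)
data: for each of J independent genetic variants, a per-allele association
with the exposure, gamma_hat_j (SE sigma_Xj), estimated in one sample, and
a per-allele association with the outcome, Gamma_hat_j (SE sigma_Yj),
estimated in a non-overlapping sample, so the two sets of sampling errors
are independent.  Under the instrumental-variable assumptions and
linearity/homogeneity of effects, each variant identifies the same causal
effect theta, and its ratio (Wald) estimate is

    theta_hat_j = Gamma_hat_j / gamma_hat_j.

All estimators require the dataset to be *oriented* first: effect alleles
chosen so every gamma_hat_j > 0 (flipping the signs of both associations
for a variant is a relabelling of its alleles and leaves every estimator
invariant).  A variant with gamma_hat_j = 0 has no defined orientation or
ratio estimate and is rejected (or dropped explicitly with
`drop_null_instruments`, since silent exclusion would change J and every
downstream degree of freedom).  Allele harmonization between the two
samples is assumed done upstream; allele columns are echoed, never
interpreted.

## Estimators

**Ratio SE.**  The default is the first-order delta-method SE,
se(theta_hat_j) = sigma_Yj / gamma_hat_j, which ignores the uncertainty in
gamma_hat_j.  This choice makes the inverse-variance weighted average of
the ratio estimates *exactly* equal to the weighted least-squares (WLS)
regression of Gamma_hat on gamma_hat through the origin with weights
sigma_Yj^-2 — an identity the test suite asserts to 1e-10.  A
second-order SE (adding Gamma_hat_j^2 sigma_Xj^2 / gamma_hat_j^4) is
available via `second_order=True` but off by default, trading a small
amount of weak-instrument honesty for that internal consistency.

**IVW.**  theta_hat_IVW = sum(w_j theta_hat_j) / sum(w_j) with
w_j = se(theta_hat_j)^-2.  Fixed-effect SE: (sum w_j)^-1/2.  The
multiplicative random-effects model keeps the same point estimate and
inflates the SE by sqrt(phi), phi = max(1, Q/(J-1)) with Q Cochran's
statistic below.  phi is truncated below at 1 so the random-effects model
can never claim more precision than the fixed-effect one; the truncation
is a modelling convention, stated here because it matters exactly when a
dataset is under-dispersed.

**Egger regression.**  WLS of Gamma_hat on (1, gamma_hat) with weights
sigma_Yj^-2.  The slope estimates theta consistently under InSIDE
(pleiotropic direct effects independent of instrument strengths); the
intercept estimates the average direct effect, and its two-sided test is
the test for directional pleiotropy.  Identification requires spread in
the gamma_hat_j: with (numerically) identical instrument strengths the
design matrix is singular and a `NotIdentifiedError` is raised rather
than returning an arbitrary pseudo-inverse solution.  The dispersion
factor for the random-effects flavour is max(1, Q_E/(J-2)) with Q_E the
weighted residual sum of squares.  The WLS is solved by explicit normal
equations so the unscaled covariance (X'WX)^-1 (fixed) and its
phi-scaled version (random) are both available; statsmodels' WLS is used
in the tests as an independent oracle, never as the implementation.

**Medians.**  The weighted median is the median of the empirical
distribution in which each theta_hat_j carries probability proportional
to w_j: sort theta_hat ascending (ties broken by variant id, so results
are permutation-invariant), form cumulative midpoints
S_j = sum_{k<=j} w'_k - w'_j/2 of the normalized weights, and linearly
interpolate between the two order statistics whose S brackets 0.5.  The
simple median is the same formula with equal weights (so an even J gives
the usual midpoint).  Note the interpolated value equals the median of
the literal discrete weighted distribution only in the dense-data limit;
the acceptance check of that equivalence therefore uses J = 2000 variants,
where adjacent ratio estimates are ~1e-4 apart.  Standard errors come
from a parametric bootstrap: resample
beta_exposure* ~ N(beta_exposure, se_exposure) and
beta_outcome* ~ N(beta_outcome, se_outcome) independently per variant
(mirroring the two-sample design), recompute the weighted median, and
take the SD over n_boot replicates (default 1000, seeded); the CI is
beta ± z_0.975 · SD.  A known limitation: because the resampling centres
on the noisy observed associations, the bootstrap dispersion of a
*quantile* statistic over-estimates its true sampling SD (measured here:
~0.049 vs ~0.042 under an all-valid null with J = 50), so median CIs are
mildly conservative — type-I error ~0.02–0.03 at nominal 0.05.  This is
a property of the standard bootstrap recipe for these estimators, not of
this implementation.

**Multivariable IVW.**  WLS of Gamma_hat on all K exposure-association
columns jointly, no intercept, weights sigma_Yj^-2; requires J > K and a
full-rank exposure matrix; with K = 1 it reduces exactly to IVW.
Covariate-association SEs are not needed (weights involve only
sigma_Yj), so they are accepted in input files but ignored.

**Scale.**  For a binary outcome analysed on the log-odds scale,
`to_odds_ratio` maps an estimate and its CI through
OR = exp(beta · exposure_sd), where `exposure_sd` converts per-unit to
per-SD effects (e.g. 1.05 log-CRP units per SD).  Scaling is applied to
the final pooled estimate, not per variant; the two orders differ only by
which constant multiplies the estimator, and the package documents and
uses this one.

## Heterogeneity and outliers

Cochran's Q = sum_j w_j (theta_hat_j - theta_hat_IVW)^2 is chi-squared
with J-1 df under homogeneity; I^2 = max(0, (Q - df)/Q), defined as 0
when Q = 0, is reported as a fraction internally and a percentage in
reports.  Each variant's contribution q_j is returned; pruning removes
variants with q_j above the 0.95 quantile of chi-squared(1) (3.84).  The
default is a single pass (contributions computed once, all offenders
removed together); an iterative mode removes the single largest offender
and recomputes, because a gross outlier inflates theta_hat_IVW and can
mask a co-outlier.  Both record the removal trail, and pruning refuses to
go below two variants.

## Subset robustness

Leave-one-out, systematic leave-k-out (all C(J,k) subsets in
lexicographic order; capped at 10^6 with a pointer to random subsets),
and random omission of round(J · fraction) variants (round-half-to-even)
n_reps times under a fixed seed.  A subset on which the chosen estimator
fails (e.g. Egger after the only strong instrument is removed) is
recorded with a failure flag and excluded from the sign-fraction
summaries with a logged count — silent omission would bias the spread.
The ordered presentation sorts by signed estimate, ascending.

## Synthetic data generator

The generator works directly on the summary-statistic scale — every
method consumes only summary data, so simulating individual-level
genotypes would add no information.  Per variant: true instrument
strength gamma_j ~ Uniform(gamma_range); direct effect alpha_j = 0 for
valid variants; for the first ceil(J · invalid_fraction) variants
(deterministic by index, so truth records are reproducible):

- balanced:        alpha_j ~ Normal(0, scale^2)           (InSIDE holds)
- directional:     alpha_j ~ Uniform(0, scale)            (InSIDE holds)
- inside_violated: alpha_j = rho · (gamma_j - mean gamma) · scale
                              + Normal(0, (scale/2)^2)    (InSIDE broken)

True Gamma_j = theta · gamma_j + alpha_j; observed associations are
independent normal draws around (gamma_j, Gamma_j) with SDs
(se_exposure, se_outcome) — the two-sample structure.  Defaults (J = 50,
gamma in U(0.1, 0.3), se_exposure = 0.005, se_outcome = 0.05,
pleiotropy scale 0.1) emulate genome-wide significant instruments from a
large exposure GWAS (instrument F-statistics in the hundreds, so
weak-instrument bias is negligible) paired with a well-powered outcome
GWAS.  What the generator does *not* emulate: linkage disequilibrium
between instruments, sample overlap, winner's-curse selection of
instruments, allele-frequency structure, or non-collapsibility of odds
ratios — so passing simulation checks speak to estimator correctness
under the stated model, not to robustness against those real-data
complications.

Per-replicate seeds are derived from the master seed by a counter scheme
(`SeedSequence(master, spawn_key=(i,))`), so any single replicate can be
regenerated in isolation.  `operating_characteristics` reports the
rejection rate at alpha (with its binomial Monte Carlo SE), mean
estimate, bias and RMSE, counting and excluding failed replicates.

## Numerical and design choices

- CIs and p-values are normal-approximation throughout, including Egger
  (keeping all methods comparable); with J around 50 the difference from
  t(J-2) reference amounts to ~+0.5–1 point of size for Egger.
- Near-singularity is detected by a condition-number bound (1e12) on
  X'WX rather than exact equality, so datasets that are *numerically*
  unidentified fail loudly too.
- Ties in theta_hat_j are broken by variant id in the median sort; all
  estimators are invariant to variant order.
- The directional-pleiotropy wrapper defaults to the
  multiplicative-random Egger model, since heterogeneity is expected
  whenever pleiotropy is present at all.
- Monte Carlo problem sizes in the tests and acceptance script (500
  replicates for recovery, 1000 for error rates, n_boot 200–500 inside
  simulations) were chosen so Monte Carlo error is a small fraction of
  the quantities being checked while the whole suite runs in minutes on
  one CPU.

## Known limitations

- Conservative median CIs (see above).
- First-order ratio SEs understate per-variant uncertainty when
  instruments are weak; the second-order option exists but changes the
  IVW/regression identity into an approximation.
- No support for correlated variants, overlapping samples, or
  individual-level-data estimators (two-stage least squares, LIML,
  L1-penalized); no covariate-screening workflow (it needs
  covariate-level association data not modelled here).
- The Egger slope's consistency argument is asymptotic in both sample
  size and, when the direct-effect/strength correlation is only zero in
  expectation, the number of variants; with few variants its CIs are
  wide and its point estimate volatile (visible in the examples).
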