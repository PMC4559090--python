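# Methods

## Models

**LQ isoeffect arithmetic.**  A fractionation regimen (d Gy × n) has
biologically effective dose BED = n·d·(1 + d/(α/β)); multi-regimen courses sum
BED over their regimens.  Inverse conversions are closed-form: at fixed dose
per fraction, D = BED/(1 + d/(α/β)); at fixed fraction number, D is the
positive root of D²/(n·α/β) + D − BED = 0,

    D = [−n·α/β + √(n²(α/β)² + 4·n·(α/β)·BED)] / 2.

Total dose and fraction number are treated as continuous in inverse solves (no
rounding to whole fractions), matching how isoeffective doses are quoted in
the tolerance-dose literature.  No overall-treatment-time, dose-rate or
incomplete-repair corrections are applied.

**Rat isoeffect estimation.**  Each of six rat data sets is a curve of
(D50, n) points — the total dose at 50% myelopathy incidence in n fractions.
Two estimators of (α/β, BED50) are provided:

* *linear* — unweighted OLS on the reciprocal-dose plot
  1/D50 = 1/BED50 + [1/(BED50·(α/β))]·(D50/n); BED50 = 1/intercept,
  α/β = intercept/slope.  This is the classical Fe-plot method; it is kept
  deliberately uncorrected for errors-in-variables because it is the
  convention the per-study reference values were produced with.
* *non-linear* — least squares of observed D50 on the positive-root isoeffect
  solution D50(n; α/β, BED50), initialized from the linear fit.  On noiseless
  LQ data the two coincide; under multiplicative noise on D50 they may
  diverge, because the linear transformation propagates the D50 error into
  both plot coordinates.

Linear-fit CIs use the delta method on (1/b₀, b₀/b₁) over the OLS coefficient
covariance, with a seeded parametric bootstrap available as a cross-check
(the CI construction behind the reference values is not documented, so point
estimates are primary and CI comparisons are tolerance-based).  Non-linear
CIs come from the asymptotic covariance of the least-squares estimator.

**Normalization and the single-fraction reference.**  Inter-study calibration
error (small-animal dosimetry; the uncorrected kilovoltage quality factor,
up to 1.12 at 50 kV) is removed by rescaling each data set so its
single-fraction D50 equals a common reference.  `normalize()` defaults to the
grand mean of the six single-fraction D50s (22.48 Gy for the packaged table).
One subtlety matters and is easy to miss: rescaling *all* doses by c rescales
both pooled estimates by c, so the reference is substantive.  The published
normalized results for this compilation are reproduced not at the 22.48 Gy
raw mean but at 20.07 Gy = 22.48/1.12 — the mean corrected by the kilovoltage
quality factor; every published per-study normalized estimate back-solves to
a reference of ≈20.0 Gy, and the published pooled fit (α/β = 4.1,
BED50 = 119) itself implies a fitted single-fraction D50 of 20.1 Gy.
`published_reference()` returns the quality-corrected mean, and the
reproduction pipeline uses it; analyses of new data should choose the
reference deliberately.

**Logistic BED dose-response.**  Cohorts contribute binomial outcomes
(events/total) at known courses; incidence is
PRIM = 1/[1 + (BED50/BED)^k], linear on the logit scale in ln BED with slope
k.  α/β enters through every cohort's BED, so (α/β, BED50, k) are estimated
jointly.  Inversion is closed-form: BED_p = BED50·(p/(1−p))^{1/k}; risk-level
physical doses compose this with the LQ inverse solves at the fitted α/β.

## Estimators for the cohort fit

The loss function behind the published cohort fits is not documented, and the
choice matters for this data — the cohorts span totals from 2 to 524, and the
extreme observed proportions (0% and 100%) are informative.  Three estimators
are implemented:

* `logit` (default): unweighted least squares of the empirical log-odds on
  the model logit.  Cohorts at exactly 0% or 100% have no finite log-odds and
  receive half an event (p̃ = 0.5/t resp. 1 − 0.5/t), the standard convention
  for plotting dose-response data on a logit scale.  This is the convention
  under which the packaged tables reproduce the published point estimates for
  the large-animal group (4.0, 111.0 vs 3.9, 112), the human group
  (3.5, 115.6, 9.5 vs 3.7, 111, 10.4) and the combined group
  (3.9, 113.1, 8.7 vs 3.9, 111, 10.5) — and whose profile interval for the
  combined group's α/β, (2.9, 5.0), matches the published (3.0, 4.9) almost
  exactly.
* `ml`: binomial maximum likelihood — the statistically preferred estimator
  when cohort sizes should carry weight.  Note that it does *not* reproduce
  the published estimates (its optima sit near α/β ≈ 2.8–3.2 with higher
  BED50), because the very large zero-event human cohorts dominate the
  likelihood; it is the right tool for prospective analyses and for the
  simulation-calibration tests.
* `ls`: unweighted least squares on raw proportions, for sensitivity
  analysis.

One published number resists all of this: the large-animal group's slope
k = 12.  Conventions that reproduce that group's (α/β, BED50) = (3.9, 112)
give k ≈ 7.6–9.1; conventions that give k ≈ 12 put (α/β, BED50) at
(3.5, 121).  An extensive sweep (maximum likelihood, proportion-space and
weighted least squares, Pearson χ², robust IRLS, dose-direction and
orthogonal-distance regression, several zero-cell rules, leave-one-out data
variants) found no estimator with a stationary point at (3.9, 112, 12); the
corresponding acceptance assertion is left failing rather than fudged.

**Optimization** is a deterministic multi-start — α/β ∈ {1,2,4,8} ×
BED50 ∈ {80,110,140} × k ∈ {5,10,20} — refined by trust-region least squares
(`logit`/`ls`) or Nelder-Mead in log-parameters (`ml`).  No random restarts;
identical inputs give identical fits.

**Confidence intervals** are computed by profiling: the likelihood-ratio χ²₁
threshold for `ml`, the F-based residual-sum-of-squares threshold
SSE·(1 + F₀.₉₅(1, n−3)/(n−3)) for the least-squares estimators.  Profile
intervals are naturally asymmetric — the sparse human design produces a
strongly right-skewed α/β interval, as expected when only two cohorts carry a
large dose per fraction.  Symmetric Wald intervals are reported alongside.
An open bound (profile never crossing the threshold within the search range)
is reported as NaN rather than an arbitrary cap.

## Identifiability and degenerate inputs

The cohort fit requires ≥4 cohorts spanning ≥2 distinct dose-per-fraction
values; with a single fraction size, α/β and BED50 are perfectly confounded
and the fit refuses to run.  Zero BED predicts zero risk (the model's limit).
The Fe-plot fit refuses data whose transformed coordinates give a
non-positive intercept or slope, since no positive (α/β, BED50) exists there.
Rat datasets need ≥3 points (two parameters) and exactly one single-fraction
point for normalization.

## Synthetic data

`simulate_rat_experiment` draws, per data set, one lognormal calibration
factor (default CV 10% — the between-study error normalization is meant to
remove) and a lognormal per-point residual on each D50 (default CV 5%,
typical of quantal dose-response assays with 5–10 animals per dose group),
applied to exact LQ isoeffect doses.  `simulate_cohorts` draws binomial
events at the model's own probabilities on an arbitrary (course, total)
design; the default design is the packaged combined-group design with truth
(3.9, 111, 10.5).  Both generators are bit-reproducible given their seed and
emit the same objects/CSV schemas as the packaged tables.

What a green simulation test establishes: that normalization removes
calibration-type error (and reduces estimator variance), that the estimators
recover the truth as information grows, and that the ML profile intervals
approximately attain nominal coverage on the real, unbalanced design.  What
it does not establish: robustness to latency/censoring of myelopathy onset,
volume effects, or dose-uncertainty structure beyond multiplicative lognormal
noise — none of which are modelled.

## Known limitations

* The default `logit` estimator weights every cohort equally; it matches the
  published analysis but is inefficient for the huge zero-event cohorts.
  Conclusions that depend on cohort weighting should be checked with `ml`.
* Fixed follow-up is assumed; shorter-follow-up studies (the cervical rat
  subgroup) systematically miss late events, which is the likely cause of
  the cervical/thoracolumbar difference and is not modelled.
* No volume effects, partial-cord irradiation, equivalent-uniform-dose
  conversion, or setup-uncertainty convolution: applying the fitted curve to
  stereotactic treatments with steep cord gradients is out of scope.
* All doses are physical Gy at the cord; no dose-rate corrections.
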