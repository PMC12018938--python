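# Methods

`immunoprofile` re-implements, as a tested pipeline, a multi-assay
immune-profiling comparison between people living with HIV (PLWH) and people
without HIV (PWOH) who recovered from SARS-CoV-2 infection. The package
works end to end on synthetic cohorts, so every stage can be exercised and
calibrated without access to the original participant-level data.

## The synthetic cohort

The generator (`immunoprofile.simulate`) draws cohorts with the structure
the downstream analysis assumes. Defaults are the study conditions: 216
PWOH and 43 PLWH; three COVID-19 severity strata (asymptomatic, symptomatic
outpatient, hospitalized) allocated by largest-remainder at the observed
cohort proportions 59:101:99; 56 markers grouped into assay families
(binding IgG1/IgG3/IgA against SARS-CoV-2 and endemic-CoV antigens, MSD
IgG, neutralization, functional-antibody percents, B cells, T cells; 14 of
the 56 are endemic-CoV markers); days since diagnosis uniform on 13–131;
and Table-1-like covariate imbalances (male fraction 0.50 vs 0.837, current
smoking 0.088 vs 0.302, US region 0.49 vs 0.69, age means 49 vs 45.8).

Marker log-magnitudes follow a one-factor-per-block latent model

    log y = mu + delta(group, severity) + X beta + lambda_b f + eps,

with `lambda_b = sqrt(rho_group)` and `Var(eps) = (1 - rho_group)` so that
markers within an assay family correlate at `rho_group` and have marginal
SD 1 on the log scale. A single knob per HIV group controls "coordination
strength"; the PLWH default (0.25) is below the PWOH default (0.5) to
emulate the weaker coordination of responses in PLWH. The latent-factor
construction guarantees a positive-definite covariance by construction. A
full covariance is deliberately not exposed: the real marker–marker
covariance is unknown, so the synthetic defaults are plausible rather than
calibrated, and network-level results on synthetic data are read as
operating characteristics, not as reproductions of the published network
sizes.

Group effects are injected as per-marker, per-severity log geometric-mean
ratios. The `trio_scenario` preset encodes the symptomatic-outpatient
classification scenario: 85 PWOH vs 16 PLWH, two depressed B-cell markers
(log-GMR log 0.25) and one elevated endemic-CoV IgG1 marker (log 2.84) —
the magnitudes of the largest adjusted group differences reported for such
markers. Missingness is completely at random (the original missingness
mechanism is unstated); covariate effects on log-magnitudes default to
small values so that confounder adjustment is actually exercised.

What the generator does not emulate: assay-level measurement error
structure (plate effects, censoring at assay limits), non-Gaussian
marker distributions beyond log-normality, missingness that depends on
magnitude, and any marker–covariate interaction. Passing calibration tests
on these cohorts therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to those features of real
data.

## Assay readout math

Closed-form readouts live in `immunoprofile.assay`: percent neutralization
and percent ACE2 blocking (both affine in the sample signal), ADCP scores
(sample MFI x positive frequency over the PBS-control product), AU→BAU
conversion with the WHO-standard factors 0.00236 / 0.0272 / 0.00901
(nucleocapsid / RBD / spike), and positivity cutoffs from seronegative
panels under three conventions: max(95th percentile, floor),
mean + 3 SD (optionally after truncating negatives to zero), and
max(95th percentile, 3 x median). Percentiles interpolate linearly between
order statistics (the convention is fixed here; sample SD uses the n−1
denominator).

ID50/ID80 titers come from a four-parameter logistic fitted on log
reciprocal dilution by bounded least squares (asymptotes in [−10, 110]),
inverted at the 50% or 80% level. Calls with maximum percent inhibition
below 10% are negative and get titer 5; a positive call whose estimation
fails — non-convergence, an upper asymptote below the target level, or an
inverted titer outside the tested dilution range — gets titer 10. The
original fitting software's loss and convergence rules are unstated, so
"estimation failed" is operationalized here as above.

## Normalization

`normalize_markers` applies five steps in a fixed order:

1. **Deselect** markers with pairwise |Spearman rho| > 0.95
   (pairwise-complete); of an offending pair, the member with the larger
   mean |rho| to the remaining markers is dropped (ties to column order).
2. **log10-transform** flagged markers (binding, neutralization, B- and
   T-cell families), flooring nonpositive values at half the smallest
   positive observed value. The base is immaterial after standardization.
3. **Impute** missing cells by chained equations with L1-penalized linear
   regressions (scikit-learn `IterativeImputer` with `LassoCV` over the
   fixed grid 1e-8…1, median initialization, ascending-missingness order,
   10 cycles, seeded). Observed cells are never altered; markers more than
   50% missing are refused.
4. **Residualize days**: per marker, OLS of y on days since diagnosis and
   subtraction of the slope term only (y − βx), pooled over all
   participants.
5. **Standardize** each marker to mean 0, SD 1.

## Per-marker comparisons

Magnitudes are compared by log-linear regression (OLS on log-magnitude;
exponentiated coefficients are geometric mean ratios with t-based CIs) and
response rates by Firth penalized logistic regression, both adjusted for
severity, age, sex, region, smoking, and days since diagnosis.
Severity-stratified HIV effects come from linear contrasts of a model with
an HIV x severity interaction; a contrast whose stratum lacks both groups
is reported as undefined rather than raised. q-values are
Benjamini–Hochberg within each assay family, and a comparison is flagged
significant when p ≤ 0.05 and q ≤ 0.2.

The Firth fit maximizes the Jeffreys-penalized likelihood by Newton steps
on the hat-value-modified score with step-halving (tolerance 1e-6, 50
iterations), which keeps estimates finite under complete separation; on a
saturated 2x2 design the coefficient equals the half-count-adjusted log
odds ratio, which the tests use as a closed-form oracle. Inference is Wald
by default — profile-penalized-likelihood intervals are not implemented;
Wald is adequate at the sample sizes simulated here. For descriptive
cohort tables the package provides the Pearson chi-square (Yates-corrected
with flooring for 2x2 tables only — the convention that reproduces all four
published 2x2 p-values) and the Welch unequal-variance t-test, which
matches the published continuous-variable p-values better than the pooled
variant at these unequal group sizes.

## Global profile test

Participants are ranked per marker (average ranks on ties) and scaled by
(rank − 1)/(n − 1); group-by-stratum mean quantiles form the polar-plot
table. The global two-sample test is a direction-projection-permutation
(DiProPerm) construction: direction = unit-normalized difference of group
mean vectors, projection scores compared by a two-sample t statistic, and a
null distribution from B label permutations with the direction recomputed
each time; p = (1 + #{perm ≥ obs})/(1 + B), one-sided, so p is valid and
bounded below by 1/(B+1). The original publication names the test without
defining its variant; the mean-difference direction with a t statistic is
the canonical choice, so the published p-values (0.014, 0.025, 0.93, 0.14)
are structural reference points rather than exact targets. Default
B = 1000, seed mandatory.

## Correlation networks

Spearman matrices are computed per HIV group (and stratum). Pair p-values
use the exact permutation null when n ≤ 10 and the data are tie-free, and
the t approximation t = rho sqrt((n−2)/(1−rho²)) otherwise; at the cohort's
group sizes (16–216) the approximation error is negligible for the filters
used. The restricted network keeps an edge when the BH q-value over all
m(m−1)/2 pairs is below 0.10 and |rho| > 0.70; markers are clustered by
Girvan–Newman edge-betweenness removal, cutting the dendrogram at maximum
modularity (ties toward fewer clusters), with isolated markers as
singletons.

The unrestricted network size is (1 − pi0) x m(m−1)/2, with pi0 from
Storey's smoother (lambda grid 0.05…0.95 step 0.05, cubic fit evaluated at
the largest lambda, clipped to [0, 1]); a fixed-lambda 0.5 estimator is
available behind a switch. Reported sizes and average degrees
(2 x size / m) round to the nearest integer, the convention consistent with
all published size/degree pairs.

Group differences in a network statistic are assessed by drawing R
subsamples (default 10,000) without replacement from the PWOH rows of a
stratum, each of the PLWH sample size, recomputing the statistic, and
reporting Prob(PWOH > PLWH) with strict inequality (ties count as
non-exceedance). Subsamples on which the statistic is undefined are
excluded with a logged count. Under exchangeability the probability for a
single PLWH draw is its quantile in the subsampling distribution, so the
calibration tests average it over replicate datasets, where it must center
on 0.5.

## Classification

Stage 1 repeats (default 200 times) a random-forest recursive feature
elimination: markers are ranked by full-data importance, a ladder of subset
sizes (m halved down to 1, plus sizes 1–10) is scored by stratified k-fold
CV-AUC of a refit forest, and the best-size subset recorded (ties to the
smaller size). Markers appearing in more than 90% (configurable within the
90–95% convention) of best subsets survive; if more than 20 survive the
procedure recurses on the survivors.

Stage 2 runs backward elimination under a super learner: random forest,
RBF-kernel SVM and extremely randomized trees, rank-scaled per fold and
blended with convex weights chosen on the 2-simplex (grid resolution 0.05)
to maximize the AUC of the out-of-fold predictions. Two guards keep the
reported CV-AUC honest: the weights scoring each fold are fitted on the
other folds' out-of-fold predictions only (leave-one-fold-out), and after
the greedy search — which removes, at each step, the marker whose removal
maximizes mean CV-AUC and stops when no removal maintains it — the final
subset is re-cross-validated on folds the search never used. Without these
guards the maximized search criterion overstates null performance
noticeably. Class imbalance is handled by stratified folds only. The 95%
CI is a normal approximation over the repeat means.

Two caveats are inherited from the design itself: selection and evaluation
share one dataset, so even the re-evaluated CV-AUC of a selected subset
carries the chance associations that drove the selection (this is why the
null-calibration check is run at n = 300 with few candidates, where that
bias is small relative to the band), and published CV-AUC values (0.756,
0.754, 0.81, 0.85) depend on the real cohort, so the acceptance surface for
the classifier is behavioral: null calibration and planted-signal recovery
at the study's 85 vs 16 group sizes.

## Problem sizes used in tests and the acceptance script

Calibration checks run at reduced resampling sizes chosen as the package's
own defaults for a quick verification pass: 500 null simulations for
type-I error and DiProPerm calibration (B = 200), 300 simulations for CI
coverage, 100 simulations for pi0-based size recovery (756 planted pairs —
two 28-marker blocks — at n = 200, a planted count in the range of the
unrestricted sizes such cohorts produce; the smoother carries a small
additive bias of ~2% of all pairs, so relative recovery is only meaningful
for planted counts well above that), 40 replicate datasets x R = 50 for subsampling
exchangeability, 25 RFE repeats for the classification scenario, and 5
permutation runs for classifier null calibration. All counts scale up by
configuration for full-fidelity runs (R = 10,000, B = 1000, 200 repeats).

## Known limitations

- Wald (not penalized-likelihood-ratio) inference for Firth fits.
- The exact Spearman null is enumerated only for tie-free n ≤ 10.
- The pi0 smoother's lambda grid and evaluation point are fixed; unrestricted
  sizes are sensitive to this choice, so cross-study comparisons of absolute
  sizes should use identical settings.
- MIMOSA-style T-cell positivity calling is out of scope; response calls are
  inputs.
- Plotting is intentionally minimal: the package emits the underlying
  tables (polar-plot table, edge lists, ROC points) rather than figures.
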