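# Methods

This package is a controlled test-bed for *cellwise* error detection in
observational anthropometric data: it simulates a growth cohort whose
ground truth is known, plants errors of defined shapes in single height
cells, and measures how well eight screening rules recover them.  This
note records the models, the concretizations chosen where a published
description leaves latitude, and what the results do and do not show.

## Cohort simulation (LMS model)

Height and weight are drawn from the LMS (Box-Cox) family used by
growth references: for age/sex-specific parameters L (Box-Cox power),
M (median) and S (generalized coefficient of variation), a measurement
at standard-normal deviate Z is

    x = M (1 + L S Z)^(1/L),     x = M exp(S Z) as L -> 0.

The implementation evaluates `exp(log1p(L*S*Z)/L)`, which stays
accurate as L approaches 0 (agreement with the limit form is below
1e-6 at L = 1e-8).  A deviate with `1 + L*S*Z <= 0` is outside the
Box-Cox domain; `lms_value` raises, while the cohort simulator redraws
such a Z (this needs |Z| above roughly 4 even for strongly skewed
weight tables with L near -2, so the redraw probability is below 1e-4
per record and exactly zero for the built-in table, which has L = 1).

Cohorts have equal numbers per (age-month, sex) group over ages 24-240
months, with any remainder allocated round-robin in (sex, age) order so
group sizes are seed-independent and differ by at most one.  Heights
are rounded to whole centimetres: the digit-manipulation error patterns
("skip last digit", "swap last digits") are only well defined on a
digit string, and integer centimetres is the simplest faithful
representation.  Weight stays continuous and enters all analyses as its
natural log, which symmetrizes its right-skewed distribution.  The Z
deviates for height and weight are independent within a record; the
shared age/sex structure already induces the strong height-weight
correlation (about 0.93 in the default cohort), and no further
within-person correlation mechanism is modelled.

Parameter tables are read from CSV in the CDC growth-chart dialect
(sex coded 1/2, `Agemos`, L, M, S columns, extra percentile columns
ignored; rows under 24 months dropped).  A **built-in synthetic
stand-in table** ships with the package so that nothing requires a
download: L = 1 (no within-age skew), M piecewise-linear in age between
per-sex anchor medians chosen once from standard growth-reference
knowledge, and constant S (0.042 for stature, 0.15 for weight).  The
stand-in reproduces the scale and age/sex structure of chart-based data
(default cohort: height median 144 cm, MAD 31, range ~75-207) but not
two features of real references: the Box-Cox skew of weight (its
log-weight tail is shorter) and the age-varying S.  Detectors that
reward elliptical, symmetric data — DDC and the robust distances —
therefore perform somewhat *better* here than they would on chart-based
simulations, which matters when comparing numbers to published
chart-based results (see "Fidelity" below).

## Error patterns

Exactly `round(prevalence * n)` height cells (half-up rounding; 100 and
500 cells at the study's 2% and 10% on n = 5000) are selected uniformly
without replacement and altered; every other cell is bit-identical
before and after.  The four patterns, in decreasing detectability:

* **skip_last_digit** — `h -> floor(h/10)`; a gross transcription error
  (176 becomes 17).  Values below 10 cm are rejected as degenerate.
* **swap_last_digits** — exchange the final two digits (163 becomes
  136).  A cell whose last two digits are equal keeps its value but is
  still recorded as an error in the mask, which caps the attainable
  sensitivity for this pattern; this is faithful to "the digits were
  swapped" as the generating process.
* **add_shift** — add a constant (default 40 cm, about 1.46 SD of the
  default cohort's height distribution), mimicking unit or calibration
  errors.
* **sample_first_percentile** — replace the value by a draw from
  Normal(M, M·S) truncated above at the age/sex-specific first
  percentile `P1`, by inverse-CDF sampling, rounded to whole cm.  The
  untruncated mean and SD are a concretization: (M, M·S) is the natural
  normal approximation to the age-specific LMS distribution.  These
  errors are plausible heights for the age and are only suspicious once
  weight is considered.

## Detectors

All multivariable methods see (age, height, log-weight); the dichotomous
sex variable is excluded.  Rowwise flags from the distance methods are
attributed to the height cell, since errors exist only in height.

**Robust SDS.** `(x - median) / (1.4826 * MAD)`; cells strictly outside
(-2, 2) flag.  **Boxplot.** Type-7 quartiles; cells strictly outside
(Q1 - 1.5 IQR, Q3 + 1.5 IQR) flag.  Boundary values do not flag in
either rule.

**Bagplot.** Tukey halfspace depth is computed exactly by an angular
sweep (O(n log n) per query; candidate halfplanes start just after each
data angle or its antipode), validated against brute-force direction
enumeration.  The bag is the convex hull of the ceil(n/2) deepest
points, shrunk by raising the depth cutoff while it covers more than
floor(n/2) points — an approximation to exact depth-contour
interpolation that is adequate because only outside-fence
classification is used.  The fence scales the bag by 3 about the depth
median (the centroid of the deepest points); points strictly outside
flag.  Two bagplots are evaluated (age vs height, height vs log-weight)
and reported separately; an either-pair combined flag is not part of
any headline table.

**Mahalanobis distances.** Squared distances are compared with the
0.99 chi-square quantile at 3 df (11.345), strict inequality.  Classic
estimates are the sample mean/covariance.  MCD uses a FastMCD-style
search: 500 random (p+1)-seeds, concentration C-steps to convergence
(determinant change < 1e-9 or 100 iterations), best determinant wins,
h = floor((n+p+1)/2), and the winning covariance is multiplied by the
normal-model consistency factor (h/n)/F_{chi2,p+2}(q_{h/n}).  MVE
evaluates 500 random (p+1)-subset shapes, inflates each ellipsoid to
cover h points, keeps the smallest volume, and rescales the shape so
the h-th distance matches the chi-square median.  Reweighting steps
(as in some R implementations) are deliberately out of scope; raw
robust estimators make the masking contrast sharper but run ~1-14%
anticonservative on specificity for pooled (non-elliptical) age-mixture
data, which is visible as MCD specificity near 86% in the default
study.

**DetectDeviatingCells.** Deterministic, four steps; the cutoff
`c = sqrt(chi2.ppf(tolProb, 1))` (2.576 at the default tolProb = 0.99)
is always derived at run time, and corrlim defaults to 0.5.

1. Robust column standardization; cells with |z| > c are set aside
   (treated as missing) for the correlation and prediction steps.
2. Pairwise correlations over rows where neither cell is aside;
   columns with |r| >= corrlim form each column's connected set,
   others are standalone.
3. Cell prediction: per pair, a median-of-ratios slope computed on
   *pairwise-median-centered* values; predictions combine connected
   columns by |r|-weighted mean and are deshrunk per column by the
   median observed/predicted ratio.  Centering before taking ratios is
   this package's concretization: without it, a corrupted cell nudges
   its column median, the exact proportionality between standardized
   columns becomes affine, and exact-dependence toys acquire residual
   spread that MAD standardization then flags on ~1% of clean cells.
   With centering, exact dependence gives exactly zero residuals and
   perfect precision/recall on such toys, while on noisy data the pair
   medians are near zero and behavior is unchanged.  Rows in which
   every connected predictor is aside borrow the aside cells as a last
   resort: a row that is extreme but internally consistent should not
   have its cells flagged for extremeness alone.  Standalone columns
   predict the column median (z = 0), which reduces to univariate
   flagging at cutoff c.
4. Residuals z - predicted are rescaled per column by their own
   1.4826·MAD (floored at 1e-12 so exact dependences still flag
   corrupted cells) and flagged at |residual| > c.  The rowwise
   statistic T_i is the mean chi-square(1) CDF of the squared
   residuals; because T is bounded by 1, a MAD-standardized cutoff can
   never fire at p = 3, so T is compared directly with the tolProb
   quantile of its null law — the Bates distribution (mean of p
   uniforms), computed from the Irwin-Hall CDF.  Under the null this
   gives a rowwise flag rate near 1 - tolProb (slightly above, since
   residuals are correlated across columns).  Rowwise flags are
   reported but enter no cellwise evaluation.

Predicted cell values are also returned in data units; their use as an
imputation/correction mechanism is out of scope and unevaluated.

## Evaluation

All metrics are cellwise on height.  Sensitivity, specificity and PPV
carry exact Clopper-Pearson 95% intervals; LR+ = Se/(1-Sp) carries the
log-method interval (these interval choices are conventions, stated
here because the quantities are often reported without them).  ROC
curves sweep every distinct threshold of a method's continuous score
(|SDS|; squared Mahalanobis distance; |DDC standardized height
residual| — boxplot and bagplot are threshold-only and excluded).  AUC
is computed in Mann-Whitney midrank form (exactly 1.0 under perfect
separation; ties count half) with a DeLong 95% interval, verified to
10 decimals against an independent reference implementation.  The
Youden point maximizes J = Se + Sp - 1; ties resolve toward higher
specificity.

## Study orchestration and seeding

One cohort is simulated per replicate; all eight (pattern, prevalence)
scenarios contaminate that same cohort, and every detector sees the
same contaminated table — paired comparisons throughout.  A single
master seed spawns independent `SeedSequence` streams for simulation,
per-scenario contamination, and the MCD/MVE searches, so adding or
removing a method never perturbs another's draws and a saved manifest
reproduces every table bit-identically.  The default grid (n = 5000,
4 patterns x 2 prevalences, all methods) runs in about two minutes on
one core; the bagplot depth computation (~3 s per scenario pair) and
the FastMCD search (~7 s per scenario) dominate.

## What passing tests show — and what they do not

The suite validates the machinery against independent oracles
(brute-force depth, pair-counting AUC, exhaustive subset enumeration
for MCD/MVE, closed-form truncated-normal sampling, hand-computed
examples) and reproduces the qualitative findings on the built-in
table: gross digit-skips are caught by every method at 2% prevalence;
the classic Mahalanobis distance collapses by masking at 10%
prevalence while MCD/MVE stay at 100%; univariate rules are nearly
blind to swapped digits and first-percentile replacements; DDC is the
strongest scorer for the hardest pattern.  Exact point values,
however, depend on the simulated distribution: the skew-free stand-in
table makes the data friendlier to robust multivariable methods than
chart-based simulations are, so point sensitivities/AUCs for the
harder patterns tend to sit above chart-based published values.  Runs
against real downloaded chart files (via `load_lms_table`) are the
appropriate check when distributional fidelity matters.

## Numerical choices and degenerate inputs

Strict inequalities at every flagging boundary.  Quartiles by linear
interpolation (type 7).  Zero-MAD columns are an error for SDS and DDC
standardization (no scores are emitted).  Collinear point clouds are a
degenerate-geometry error for the bagplot.  Singular covariances raise;
an exact-fit majority (singular best h-subset) raises rather than
returning a misleading scatter.  Ratio and deshrinkage denominators use
a 1e-6 floor; residual scales a 1e-12 floor.  The depth sweep treats
points coincident with the query as belonging to every halfplane.
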