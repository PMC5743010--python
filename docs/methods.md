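# Methods

`maizefrontier` re-implements a synthesis analysis of the relationship
between maize planting date and yield in high-yielding US production
systems.  The original study combined a national yield-contest-winner
database (n = 16171 field-years, 2011-2016) with a literature compilation
(n = 819); the contest records are not publicly deposited, so this package
pairs every analysis stage with a synthetic-data generator that reproduces
the documented statistical structure of those data.  This note records the
models, the estimators, the generator's assumptions, and the numerical
choices.

## Data model and units

A field record carries latitude (degN), planting date as 1-based day of
year (DOY), grain yield, and optional management covariates (irrigation,
tillage class CT/NT/RT, row spacing, seeding rate, N/P/K rates).  Yields
are normalised to Mg ha^-1 at 155 g kg^-1 grain moisture.  Bushel-per-acre
inputs use the maize bushel (56 lb = 25.4012 kg) and the international acre
(0.404686 ha); moisture conversion applies the constant-dry-matter rule
`y * (1 - m) / (1 - 0.155)`.  The source reports only the target moisture
basis; the constant-dry-matter rescaling is the standard agronomic
convention and is our choice.  DOY is kept on each record's own calendar
year, so the same calendar date maps to DOY values that differ by one
across leap years; we document rather than normalise this.  Records with
non-positive yield, latitude outside [20, 55] degN, or an unparseable date
are dropped and tallied in a load report.

## Stratification

Three labelling schemes:

* **Latitude groups** — 5-degree bands 25-30, ..., 45-50 degN.  Bins are
  half-open `[lo, hi)` except the northernmost, closed at 50; the source
  does not state its edge convention.
* **Yield environments** — MY `[5, 10)`, HY `[10, 15)`, VHY `>= 15`
  Mg ha^-1; below 5 is unassigned.  The VHY band is unbounded above
  (the reporting figures use "> 15"), which we adopt over the narrower
  "15-20" phrasing elsewhere in the source text.
* **Planting windows** — either the six fixed DOY map classes
  (42-88, 89-106, 107-118, 119-128, 129-148, > 148) or latitude-anchored
  VE/ER/MD/LT classes: the anchor is the group's earliest planting (or a
  configurable low quantile, which is robust to stray early records), VE
  covers the anchor plus 10 days, and each subsequent class spans the next
  11 days.

The *most frequent planting window* estimator is our reconstruction (the
source states the resulting ranges but not the estimator): build a 1-day
histogram of plantings, smooth with a 7-day centred moving average, and
return the shortest integer interval containing at least a target fraction
(default 0.5) of the smoothed mass, breaking ties toward the earliest
interval.  The published windows per latitude group (42-88, 89-106,
107-118, 119-128, 129-135) ship as constants and are the default reference
for before/within/after comparisons; the 45-50 degN published window
(129-135) and the corresponding map class (129-148) differ in the source
and both are retained.

## Variance components

Each factor (year, state, irrigation, planting date, seeding rate, row
spacing, tillage, N, P, K) is assessed *marginally*: the factor is the
grouping variable of an unbalanced one-way random-effects model and its
component is the method-of-moments (ANOVA) estimate

    sigma2_f = max(0, (MSB - MSW) / n0),
    n0 = (N - sum n_i^2 / N) / (k - 1),

truncated at zero.  Continuous covariates are discretised into quantile
bins (default quintiles) first; planting date and year are treated as class
variables level-by-level.  The residual "error and interaction" row is the
total sample variance minus the factor components, floored at zero.  Joint
mixed-model estimation (e.g. REML with all factors simultaneously) is
deliberately out of scope: the reported decomposition is the
individual-effects one, and exact agreement with any particular mixed-model
software is a non-goal.  Percent shares are `100 * component / total` and
are reported both unrounded and rounded to integers.  Note the MoM
estimator targets the superpopulation factor variance, so with few levels
and strong structure a share can exceed 100%.

## Latitude trend and window comparisons

The planting-date/latitude trend is the four-parameter logistic

    doy(lat) = A + (D - A) / (1 + exp(-B (lat - C)))

fitted by bounded least squares (asymptotes in [30, 160] DOY, steepness in
(0, 5] per degN, midpoint in [20, 55] degN) from a 3x3 multi-start grid
over steepness and midpoint with data-driven asymptote starts; the best
converged start by SSE wins and R^2 = 1 - SSE/SST.

Planting-window mean comparisons use fixed-effect one-way ANOVA with
Tukey's HSD: the pooled within-group mean square, the studentized-range
critical value at alpha = 0.05, and the Tukey-Kramer allowance for unequal
group sizes.  Letters come from the insert-and-absorb compact-letter
algorithm, ordered by descending mean; two groups share a letter exactly
when the HSD criterion does not separate them.  (The original analysis ran
a mixed model with an unstated random structure; the fixed-effect ANOVA +
HSD reconstruction is documented as a divergence.)  Error bars in the
summaries are per-class standard errors of the mean.  Management profiles
are descriptive: mean yield per window x tillage and window x irrigation
cell, and the OLS slope (with CI) of yield on seeding rate, per 1000 seeds
ha^-1, within each VE/ER/MD/LT class.

## Quantile linear-plateau frontier

The core estimator.  The attainable-yield boundary given planting date is
modelled as a linear plateau

    f(x) = P + s * max(0, x - beta),  s <= 0,

fitted at conditional quantile tau = 0.99 (configurable) by minimising
total pinball loss `rho_tau(u) = u (tau - 1[u < 0])`.

**Algorithm.**  The breakpoint beta is profiled over an integer-day grid
from `min(x) + 2` to `max(x) - 2` (planting dates are day-resolution).
For fixed beta the problem in (P, s) is a two-parameter quantile
regression with the slope sign-constrained:

* for a fixed slope the optimal plateau is an exact order statistic (the
  ceil(n tau)-th smallest of the slope-adjusted responses), so the profiled
  loss is a 1-D convex piecewise-linear function of the slope;
* small problems enumerate every pairwise candidate slope
  `(y_i - y_j)/(z_i - z_j)` plus the s = 0 boundary — exactly the vertex
  set of the underlying linear programme — and are therefore solved
  exactly;
* large problems minimise the profiled loss by a bracketing grid-shrink
  (17-point grids, interval shrink factor 8 per round) down to a slope
  tolerance of 1e-12 for point estimates.

Ties in profiled loss within 1e-9 resolve to the smallest breakpoint.  A
brute-force oracle (`frontier_oracle`, n <= 200) enumerates all candidate
lines directly and is used in the tests to certify the solver.

**Pruning.**  For n > 600 points below their 10-day bin's 0.95 yield
quantile are removed from the non-smooth part of the loss and carried as an
exact affine term (their count, yield sum, and per-breakpoint excess-day
sum).  The reduction is exact whenever every pruned point lies below the
fitted boundary; this is verified after the fit and a violation triggers an
unpruned refit.  This makes the n = 16171 fit run in well under a second
and the B = 500 bootstrap in about a minute.

**Bootstrap.**  Case resampling with replacement at the original n;
percentile 2.5/97.5 intervals for plateau, breakpoint and slope.
Replicates profile the breakpoint only within +/-30 days of the full-data
estimate, on a coarse-then-fine grid, with the slope tolerance relaxed to
1e-6 — the induced per-replicate error (< 1e-6 in the slope, <= 1 day of
grid coarseness absorbed by refinement) is negligible against CI widths.
Replicates with an unidentified slope (fewer than two resampled points
beyond the breakpoint) are retained as s = 0 and counted; above 20% a
warning is attached.

**Dataset comparison.**  Sizes are equalised by one seeded
with-replacement draw of the smaller dataset's n from the larger (an
R-replicate robustness mode returns per-replicate fits), the combined
dataset is their union, and parameters are declared "different" exactly
when the two 95% intervals do not overlap — the comparison rule stated by
the source, which is conservative relative to a formal two-sample test.
The comparison of the literature and contest boundaries uses each
dataset's own size (819 and 16171); equalisation feeds only the combined
model.

## Synthetic data generator

The generator defines the study conditions under which everything above is
tested.  Per record:

1. latitude group from a categorical mixture (default weights 0.05, 0.15,
   0.30, 0.35, 0.15 south to north, matching the documented 35-45 degN
   concentration), latitude uniform within the group;
2. planting DOY = logistic mean (A = 58, D = 122, B = 0.45 per degN,
   C = 31 degN — a ~60 DOY planting date in the mid-20s degN rising to
   ~120 DOY by 50 degN) plus Gaussian scatter (sd 7 days) plus, for 10% of
   fields, an exponential delay with mean 30 days emulating replanting and
   wet-spring postponement; rounded and clamped to [40, 200];
3. yield = `frontier(doy) * (1 - W) + management effects + N(0, 0.08)`,
   where the frontier is the configured linear plateau (contest preset:
   P = 21 Mg/ha, beta = 152 DOY, s = -0.055 Mg/ha/day; literature preset:
   P = 18, beta = 123, s = -0.055) and W is a shortfall fraction: exactly 0
   with probability 0.07 (fields that realise the boundary), otherwise
   Beta with mean 0.3165 and concentration 21 (literature preset: zero
   mass 0.06, mean 0.41, concentration 8 — lower mean, wider spread);
4. year and state random effects (sd 0.02 each, demeaned) perturb W and
   are clipped so W >= 0 — the frontier therefore remains a hard envelope
   while year/state still carry variance;
5. management covariates with realistic frequencies; their yield effects
   are additive and window-dependent, with the configured interaction
   signs: seeding-rate response negative at very-early and slightly
   positive at late planting, conventional tillage favoured early and
   (reduced/no-till) favoured late, irrigation favoured late.

Calibration targets, fixed before the test campaign: marginal mean yield
14.8 Mg/ha; the configured frontier recovered by the tau = 0.99 fit at
n = 16171 within ~2 days (breakpoint), ~0.15 Mg/ha (plateau) and ~0.003
Mg/ha/day (slope) median error; latitude-fit R^2 ~ 0.50.  The marginal
yield sd comes out ~2.6 Mg/ha, somewhat above the ~2.3 implied by the
published total variance: the late-planting delay tail (required for the
post-breakpoint decline to be identifiable at tau = 0.99) adds
frontier-decline variance.  All distributional shapes are tunable.

What the generator does *not* emulate: weather, soil, genotype, spatial
autocorrelation between counties, year-by-latitude interactions, or any
systematic within-window yield trend other than the frontier and the
configured covariate effects.  Passing tests therefore certify the
estimators under the documented structure, not the full messiness of field
data.

## Numerical and design notes

* Quantile definition: the minimiser of the pinball loss in the plateau is
  taken as the lower optimal order statistic when the minimiser set is an
  interval.
* Quantile crossing: boundaries fitted independently at different tau can
  cross in sparse extrapolation regions; monotonicity in tau is verified
  on dense data over the inner DOY support only.
* Degenerate inputs: a single factor level yields a zero variance
  component with a warning; a window class with fewer than two records is
  excluded from the HSD comparison with a warning; frontier fits require
  n >= 10 and a DOY span >= 10 days.
* Reported frontier parameters in the acceptance report are medians over
  five generator replicates — a single n = 819 realisation carries up to
  ~10 days of breakpoint sampling error.
* All stochastic stages consume explicit seeds; the pipeline manifest
  records every seed, package versions, and stage timings.  Problem sizes
  used by the test suite (n between a few hundred and 16171; B between 200
  and 500) are the package's own defaults for these analyses.
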