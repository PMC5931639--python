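# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices made where the method
left them open.

## The estimation problem

The unit of analysis is a primary urban area ("city"): a contiguous
city-region built from one or more local authorities. For each city we
have (a) a predictor block derived from a random sample of street
images — the number of images containing at least one pedestrian,
cyclist, parked cycle, car, motorcycle or bus, plus the monthly
distribution of image dates — and (b) outcome measures from routine
surveillance: census commute mode shares (percent of commuters, home
workers excluded) and survey-reported past-month walking and cycling
(prevalence, days per week, hours per day, for all-purpose and
transport-purpose activity). The task is to predict each outcome from
the image-derived block and to quantify out-of-sample accuracy with
n ≈ 30 cities.

## Sampling design

Image locations are drawn in three stages: one uniformly-positioned
point per road-network link; a simple random subsample of those points,
oversampled 100% relative to the target because many locations lack a
usable panorama; and a year-prioritised selection of one archived
panorama per location (preference order 2011 > 2012 > 2010 > 2009 >
2008, matching the census/survey reference period), with a seeded
random subset filling the marginal year. Each selected location
contributes two images at opposite headings (0° and 180°); four
headings would double-count road users in overlapping fields of view.

Sample-size adequacy is assessed by a stabilisation criterion: the
running per-mode proportion of images with at least one observation
must vary by less than `tol` (max − min) over a trailing window of
images. The window (100 images) and tolerance (0.005) are this
package's formalisation — the original analysis judged stabilisation
from plots without stating a rule. Locations with panoramas only
outside the priority years are excluded entirely. Within a partially
needed year the filler subset is seeded-random; no within-year ordering
is defined by the method, and this choice is recorded as an assumption.

## Regression families

Proportion outcomes (mode shares, activity prevalences) use **beta
regression** in the mean–precision parameterisation:
`y ~ Beta(mu*phi, (1-mu)*phi)` with `logit(mu) = x'beta` and a single
constant precision `phi > 0` estimated on the log scale (no dispersion
covariates; the original analysis used package defaults, which are the
same constant-precision model). Estimation maximises the exact
log-likelihood by BFGS with analytic gradients, started from OLS on
`logit(y)` with a method-of-moments precision start. Convergence is
declared when the gradient infinity-norm is below
`1e-5 * (1 + |loglik|)`; non-converged fits are returned flagged, never
silently. Boundary observations (`y` exactly 0 or 1) are rejected with
instructions to apply the squeeze `y' = (y(n-1) + 0.5)/n`; none occur
in practice. Percent-scale outcomes are divided by 100 before fitting;
month-share predictors stay on the 0–100 percent scale (an interpretive
choice — the published coefficient magnitudes are not internally
consistent on this point, and the alternative 0–1 scaling simply
multiplies those coefficients by 100).

Right-skewed continuous outcomes (days of cycling, skewed by a few
high-cycling cities) use **Huber M-regression** fitted by IRLS with
tuning constant k = 1.345 (95% Gaussian efficiency) and scale
re-estimated each iteration by the MAD with consistency constant 1.4826
(defaults of the standard implementations, unstated in the original).
Convergence: max coefficient change < 1e-8. Remaining continuous
outcomes use OLS.

Model diagnostics for the beta family use standardised weighted
residuals on the logit scale,
`r_t = (y*_t − mu*_t) / sqrt(v_t (1 − h_tt))` with
`y* = logit(y)`, `mu* = psi(mu phi) − psi((1−mu) phi)`,
`v = psi'(mu phi) + psi'((1−mu) phi)` and `h` the weighted-hat-matrix
leverage. This is the "standardised weighted residual 2" variant; the
original reports only that the package default was used, and if its
printed residual summaries disagreed materially on the deposited data
the variant choice should be revisited rather than forced.

## Cross-validation and variable selection

Out-of-sample accuracy uses leave-one-out cross-validation: each city
is predicted, on the response scale, from a model fitted to the other
n − 1. Summaries: PRESS (sum of squared held-out errors), MAE and MDAE
(mean/median absolute error), and for beta models the mean and median
absolute standardised held-out error (leverage omitted for the held-out
point, which is not in the training hat matrix). Folds that fail or do
not converge are flagged and excluded from the summaries with a
warning.

Selection starts from a maximal model containing every presence count
whose correlation with the outcome is at least `r_min = 0.1` in
absolute value, plus every month variable correlated (same threshold)
with any presence count. It then repeatedly removes the least
significant predictor (Wald p-value above `alpha = 0.05`) whose removal
reduces the LOOCV PRESS, trying candidates in decreasing p-value order
(ties broken by larger PRESS reduction, then column order), and stops
when no removal lowers PRESS. Both thresholds are this package's
choices; the method states only "near-zero correlation" and "low
statistical significance". Selection is performed once on the full
data; LOOCV evaluates a fixed specification (non-nested selection, as
the PRESS-per-candidate procedure implies). Note that the procedure's
failure mode is irreducible: with `alpha = 0.05` a pure-noise predictor
is spuriously "significant" in about one run in twenty and is then not
a removal candidate.

The ten final model specifications are frozen in
`selection.FINAL_MODEL_SPECS` (outcome, predictors, family), including the
square-root transform of the cyclist count in the cycling mode-share
model. A predictor with no variance across the available cities (e.g. a
winter month share in a world with no winter images) is dropped with a
warning before fitting, since it would make the design singular. The
utility-cycling prevalence model uses the cyclist count untransformed,
following the published footnote that marks only the cycling mode-share
model as transformed, although the printed coefficient magnitude would
also be consistent with a square root.

## Gender split of cyclists

Cities are sorted ascending by the census male/female commuter-cycling
ratio and partitioned into k = 4 contiguous groups. The published
method states the two goals — similar within-group ratios, similar
observation totals across groups — but no algorithm; this package
enumerates all contiguous partitions (cheap for ≤ 40 cities) and picks
the one minimising the variance of group observation totals, breaking
ties by the summed within-group ratio range. Group image-based ratios
pool counts (sum of males over sum of females); survey-based group
ratios are averages of per-city ratios weighted by each city's gender
observation count. Per-city gender observation counts are not published,
so the survey-weighted columns of the published comparison table are
reproducible only qualitatively; the pooled-count ratios are exact.

## The synthetic-data generator

The generator replaces the proprietary image harvest with a world in
which the ground truth is known, so that each pipeline stage can be
verified against the quantity it is supposed to estimate. Defaults
emulate the study conditions: 34 cities; 94% panorama availability;
per-location year sets tuned so the selected mix orders
2012 > 2011 > 2009 > 2008 > 2010; a Dirichlet month mix concentrated on
March–November with near-zero winter mass; car presence in ~72% of
images and sparse cyclist/motorcycle/bus presence; census-style shares
as a logistic-normal perturbation of the true shares; survey measures
as monotone maps of the latent activity with lognormal noise; and a
cyclist gender link `male_share = logistic(a − b·log(cycle share))`
with b > 0, so gender equality rises with cycling levels.

Per-image counts are Poisson with log-rate = mode base + city effect +
month effect, then binned. The survey only ever recorded bins, so no
count distribution is identified by the data; Poisson is the simplest
choice reproducing the observed bin sparsity, and downstream analysis
uses presence only, which depends on the rate solely through
`1 − exp(−rate)`.

Street networks are jittered planar grids with a lognormal link count
matched to real network sizes (mean ≈ 22,760 links, max ≈ 124,600) and
scaled by 1/20, with the sampling plan scaled in proportion (target 500
locations from 1000 second-stage points); a floor on the link count
keeps the second stage feasible. A single global seed expands into
per-city substreams by stable hashing of the city id, so adding a city
never perturbs the others and worlds are reproducible bit-for-bit.

What the generator does **not** emulate: real geography (no CRS, no
real link-length distribution), spatial autocorrelation of road users,
within-city spatial bias of panorama years, annotator error, weather,
or time-of-day effects. Passing tests therefore demonstrate that the
pipeline recovers known structure under the stated generative
assumptions — not that the real-world effect sizes are correct; those
are checked separately against the deposited study dataset where
available.

## Problem sizes used in tests

The shared test world uses 12 cities at 200 target locations each; the
end-to-end mechanism check uses 10 cities at 500 locations (1000
images) per city, the scale at which the cyclist-count/cycle-share
correlation is expected to exceed 0.7; property suites use 8–500
observations per instance and 20–50 seeded replicates. These sizes are
the package's chosen desk-scale defaults for routine verification.

## Known limitations

- Constant-precision beta regression only; no bias correction or
  variable dispersion.
- Inference is limited to Wald p-values, which is all the selection
  loop requires.
- The deposited per-city dataset must be supplied by the user for the
  real-data reproduction; it is not redistributed with the package.
- The gender partition search is exhaustive and intended for tens of
  cities, not thousands.
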