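# Methods

## Design

`neoclim` estimates how many temperature-related neonatal deaths are
attributable to climate change, in two stages.

**Stage 1 — exposure-response.** The unit of analysis is a neonatal death
(age 0–28 days; "very early" restricts to day 0). Each death day t is
compared with the other days of the same calendar month and year that fall
on the same day of the week (3 or 4 controls). Because every case is its own
control, all time-invariant characteristics of the child, household and
location cancel by design; the weekday restriction absorbs within-week
structure, and the month/year stratum absorbs seasonality and secular
trends. Exposure is the daily mean temperature expressed as a percentile of
the location's own distribution, so populations from different climate zones
can be pooled on one axis while keeping location-specific optimal
temperatures in °C. The exposure-lag-response is a DLNM cross-basis: natural
cubic splines in percentile (boundary knots at 0 and 100) and in lag
(0–2 days), combined as a tensor product. Coefficients are estimated by
maximizing the exact conditional likelihood (one case per matched set); the
exposure-dimension knot placement is chosen by AIC over a configurable
candidate list. The minimum-mortality percentile x₀ is the grid argmin of
the cumulative (lag-summed) log relative risk, and all reported risks and
attributions are contrasts against x₀.

**Stage 2 — attribution.** For each case, the backward attributable
fraction AF = 1 − exp(−Σ_l β_{x_{t−l},l}) is evaluated twice: with the
factual exposure series and with the counterfactual series mapped through
the *same* factual percentile map, so one fitted β applies to both. Summed
AFs give attributable numbers; factual − counterfactual is the
climate-change excess; AR = m_neonat · AF_CC converts to rates per 100,000
live births (for the very-early outcome, m is scaled by the day-0 share of
neonatal deaths). x₀ is a property of the fitted model and is held fixed
when evaluating the counterfactual.

## Conventions and numerical choices

- **Percentiles.** Hazen plotting position, 100·(rank − 0.5)/n with
  mid-ranks for ties; values outside the reference range clamp to the
  smallest/largest attainable percentile. The reference sample is the
  location's factual daily series over the full study period. The Hazen
  convention is symmetric and never returns 0 or 100, which the spline
  boundary knots at 0/100 then never need to extrapolate past by much.
- **Natural splines.** Cubic B-spline basis on the given knots projected
  onto the subspace with zero second derivative at both boundary knots,
  extended linearly beyond them (first-order Taylor expansion at the
  boundary). df = interior knots + 1 (+1 with intercept). The basis spans
  exactly the same column space as R's `splines::ns` (verified in the test
  suite via Rscript).
- **Lag basis.** Natural spline over lags 0..L with one interior knot at
  exp(mean(log l)) over the positive lags — √2 ≈ 1.414 for the default
  0–2-day window — and an intercept (df 3). A degenerate window (L = l₀)
  falls back to a constant lag column, reducing the model to an ordinary
  one-dimensional spline.
- **Exposure-dimension candidates.** Default AIC candidates place 2–3
  interior knots: (25,75), (33,67), (10,90), (10,50,90), (25,50,75)
  percentiles. With tens of thousands of matched sets the pointwise CIs are
  narrow, and a single-interior-knot natural spline concentrates all
  curvature at one percentile, which can leave one arm of a U-shaped
  association with an approximation bias larger than its CI; such sparse
  configurations remain available through `var_knot_candidates` for small
  samples. Exact AIC ties resolve to the earliest candidate; candidates that
  fail (collinear design, separation) are skipped and logged.
- **Conditional likelihood.** Newton iterations with step-halving;
  convergence at relative log-likelihood change < 1e-10 and gradient
  max-norm < 1e-6, capped at 100 iterations (the coefficient count is ~6–12
  and the problem is well conditioned). The covariance is the inverse
  observed information. Degenerate inputs raise informative errors: all
  sets uninformative (case equals controls everywhere); collinear columns
  (smallest information eigenvalue below 1e-10 of the largest); complete
  separation (any |β| > 50 while the likelihood still increases, or every
  case's conditional probability within 1e-4 of 1 at convergence).
- **MMT search.** Grid argmin at 0.1-percentile resolution within [1, 99]
  (boundary artifacts of the natural-spline tails are excluded by default;
  the bounds are configurable). Ties resolve to the lowest percentile. The
  argmin is invariant to the centering used during fitting, since
  re-centering shifts the cumulative curve by a constant.
- **Heat/cold separation.** Lag contributions whose exposure lies on the
  other side of x₀ are zeroed inside the exponent (the standard convention
  of the backward-AF literature). Heat + cold = total holds exactly when all
  of a case's lagged exposures are one-sided; in mixed cases the
  second-order discrepancy is computed and reported (`side_gap`), never
  hidden.
- **Severity ranges.** Six bins bounded by the 2.5th/25th/x₀/75th/97.5th
  percentiles. Within each side, a case's side AF is allocated to bins in
  proportion to each bin's share of the side's retained log-RR sum. This
  allocation is exactly additive (bins sum to their side by construction)
  and coincides with the zeroing convention whenever all of a case's
  same-side lags fall in one bin.
- **Protective days.** Negative per-case AFs (RR < 1 over the lag window)
  are retained in all sums; truncating them would bias attributable numbers
  upward.
- **Monte Carlo.** β draws from MVN(β̂, V) per fitted dataset (V symmetrized
  and eigenvalue-clipped within 1e-10, otherwise rejected), factual and
  counterfactual burdens recomputed per draw, draws pooled across datasets
  with equal weight. Point estimates are means over all pooled draws;
  intervals are empirical 2.5th/97.5th percentiles. Default 10,000 draws;
  1,000 draws are used in the validation suites for speed. All draws are
  seeded and bit-reproducible.
- **Grid linkage.** PSUs are assigned the grid location with the nearest
  cell center by great-circle distance (no area weighting; 0.5° cells are
  large relative to typical DHS GPS displacement). Distances are rounded to
  1e-6 km so numerically equal distances tie exactly, and ties break to the
  lexicographically smallest location id, making the assignment
  deterministic and order-invariant. PSUs farther than a configurable
  maximum (default 100 km) raise an error listing them.

## The synthetic world

The generator emulates the study conditions end to end: N locations with
distinct seasonal climates (mean 13–29 °C, amplitude 2.5–9 °C, AR(1) daily
weather with autocorrelation 0.7), a counterfactual series generated first
and a factual series derived from it by adding a linear ramp reaching the
configured total warming (default 0.9 °C, so the factual-minus-counterfactual
mean over the window is 0.45 °C) — the pair therefore shares all weather
variability, mirroring how rank-preserving detrending constructs real
counterfactuals. Births are uniform over the period; on life-day d the death
probability is h₀ · exp(Σ_l w_l · logRR(percentile on day d−l)) with
h₀ = 0.0012/day (≈ 3.4% 29-day baseline mortality, a realistic high-burden
neonatal rate) and a U-shaped truth: quadratic in percentile around the
minimum (default the 50th percentile), amplitude 0.35 log-RR at ±40
percentile points, continuing linearly beyond (C1-matched) — a shape whose
curvature vanishes toward the distribution tails, as natural-spline fits
assume. Lag weights default to (0.5, 0.3, 0.2). Default scale is 10
locations × 105,000 births ≈ 40,000 neonatal deaths, of which ~34,500 fall
inside the 15-year maternal recall window (interviews are dated one day
after the period ends, so recall filtering is exercised). Every configured
temperature dataset id receives identical series — real reanalysis products
largely coincide over recent decades — so multi-dataset pooling is exercised
structurally without inventing spurious between-product spread.

What the generator does *not* emulate: spatial correlation between
locations, interannual climate modes, DHS sampling weights, reporting
omissions or date heaping, and exposure measurement error. Passing
recovery tests therefore demonstrate correctness of the estimation and
attribution machinery under the stated data-generating process, not
robustness to those real-data features.

## Validation scales and known limitations

The end-to-end suites run at two scales: full (10 locations, ~40k deaths)
for parameter recovery — the minimum-mortality percentile is recovered with
a replicate standard deviation of ~1.5 percentile points — and scaled-down
(4 locations, ~4k deaths, 1,000 draws) for the 50-replicate interval
calibration.

Pointwise 95% bands on the cumulative curve are not simultaneous bands: the
curve estimate is strongly correlated across grid points, so occasional
replicates show a whole-curve excursion in which a sustained region of the
truth sits just outside the pointwise interval. Interval calibration for
scalar summaries (the pooled attributable fraction) is the more stable
check. Model-selection uncertainty (the AIC step) is not propagated into
the Monte Carlo intervals, matching standard practice in this literature.
The conditional-likelihood approximation also ignores that a neonate is
only at risk on the days it is alive and aged ≤ 28 days within the stratum;
with daily hazards of order 1e-3 the induced bias is negligible.
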