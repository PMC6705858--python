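# Methods

This note documents the models, the synthetic survey the tests run
against, the numerical choices, and the limits of what passing tests
demonstrate.

## Survey data model

The atomic observation is a seine haul: estuary code, year, calendar
month, swept area (140 m² for the standard gear), depth, temperature,
salinity, SAV cover (percent, 10% increments), distance from shore, total
count, and up to ten measured standard lengths (mm). Hauls closer than
5 m to the shoreline are excluded before any analysis. Missing
environmental values are carried as missing and removed listwise only by
model fitting. Measured lengths are stored semicolon-delimited in one
column so a haul remains one row with a unique key; CSV round-trips are
lossless (shortest-repr floats on write, round-trip float parsing on
read).

## Density, biomass, and the aggregation ladder

Density is `100·count/area` fish per 100 m². Biomass converts each
measured length with `W = a·SL^b` and extrapolates deterministically:
haul biomass = `count × mean(measured weights)`, scaled per 100 m². The
deterministic rule (rather than resampling lengths) is reproducible and
unbiased for the haul total when the measured subsample is random. A
positive haul with no measured lengths falls back to the estuary–month
mean measured weight (logged); length–weight constants default to the
isometric baseline `a = 10⁻⁵ g·mm⁻³, b = 3`, or are fitted per estuary by
OLS on `ln W ~ ln SL`.

Monthly means are plain averages over hauls with SE = sample sd (n−1
convention) / √n; a single-haul month records a missing SE. Climatology
is the mean over years per calendar month; anomalies subtract it.
Standardized ratios divide annual means by the mean of annual means, so
equally weighted years average to exactly 1; the grand mean of monthly
entries is also reported as the long-term mean. Moving averages are
centered with truncated windows at the series edges, so annual peak
extraction sees every month.

## Synchrony

Inter-annual synchrony correlates *month-standardized* anomalies
(anomaly divided by its calendar-month sd over years). The seasonal pulse
makes raw anomaly variance strongly month-dependent; under independence
that heteroscedasticity inflates the null distribution of the Pearson
correlation (the pulse-kurtosis factor), and standardization restores the
1/√n null scale. Intra-annual synchrony correlates 12-month climatologies
at circular shifts. Lags k = 0..3 are searched in the row-leads-column
orientation (r(k) pairs x_t with y_{t+k}); the peak is the largest |r|
with ties to the smallest lag (a signed-peak option exists). The
significance bound is the large-sample white-noise threshold
z/√n_eff with a Šidák adjustment for the four lags searched
(per-lag level 1−(1−α)^{1/4}), so flagging the peak of two independent
series has familywise rate α — an unadjusted per-lag bound would flag
~4α of independent pairs. Pairs with fewer than 24 overlapping months
refuse to fit. No prewhitening or ARMA filtering is applied.

## Portfolio effects

`CVPE = mean(local CVs)/CV(aggregate)`, with CVs over annual peaks of the
3-month moving average of monthly means. The aggregate is the equally
weighted mean of member series restricted to the members' common
coverage, so local and metapopulation CVs measure the same months (CVPE
is identical under sum versus mean aggregation for complete data). Both
transforms — peak extraction or raw annual means — are available; peak
extraction is the default. Default groupings: all four estuaries, the
northern pair (AB+CK), the southern pair (TB+CH). For identical members
CVPE = 1 exactly, for n independent members it approaches √n.

## Cohort detection and growth

The December length sample pools all Decembers per estuary. Two gates
must both pass before a split: bimodality coefficient
`(g₁²+1)/(g₂+3(n−1)²/((n−2)(n−3)))` above the uniform benchmark 5/9
(bias-adjusted sample skewness g₁ and excess kurtosis g₂ — this is the
convention under which uniform = 5/9 ≈ 0.55), and a Hartigan dip test
with p < 0.05. The split threshold is the minimum of a Silverman-
bandwidth Gaussian KDE between the two largest modes — deterministic
given the bandwidth rule and free of mixture-distribution assumptions.
Fish below the threshold become "month 0" of the following year.

Growth is `ln L_t = ln L₀ + G·t` with t the calendar month (December
recruits at t = 0, so L₀ is the recruitment size), fitted by OLS to
pooled climatological mean lengths for months 4–7 (April–July), avoiding
settlement (Jan–Mar) and egress (Aug–Dec) biases. Per-year fits are
available via `monthly_mean_lengths(per_year=True)`; pooled means are
canonical.

### Dip statistic

The dip — the smallest sup-norm distance between the ECDF and any
unimodal CDF — is computed exactly by minimising over candidate modal
points. At a distinct value with cumulative fractions c_prev/c, a CDF
within distance e that is continuous there must pass through the band
[c − e, c_prev + e]. For a fixed mode, convex feasibility left of it is a
greatest-convex-minorant condition on the band targets (half the largest
gap between lower targets and the GCM of upper targets), concave
feasibility on the right is the mirror image, and the two branches must
meet: chord-extrapolation bounds (each linear in e) constrain the convex
branch's left limit from below and the concave branch's value from above,
and the smallest reconciling e is found by an exact active-constraint
iteration on the piecewise-linear equation. Correctness is established in
the test suite against (i) an exhaustive search over all modal chords
(agreement to 1e-12 at n ≤ 12) and (ii) a linear program over unimodal
CDFs. A sample with at least two distinct values has dip ≥ 1/(2n); a
constant sample has dip 0.

The dip test's null is Monte Carlo: B (default 2000) uniform samples of
the same size, p = (1 + #{dip_b ≥ dip})/(B + 1). Because the null-table
cost grows superlinearly in n, the cohort gate computes the p-value on a
seeded subsample of at most 500 points when the December pool is larger
(the dip statistic itself is reported for the full sample); for the
strongly separated cohorts the gate screens, the decision is insensitive
to this.

## Hurdle habitat model

Counts (with ln-area offset) are modelled rather than densities — the NB
likelihood needs integers and area is constant, so the ordering is
unchanged. Derived terms SAV² and SAV×temperature are built from raw
covariates first; every model column is then z-scored, so reported
coefficients are standardized (the scaling record supports
back-transformation). The presence part is logistic regression fitted by
Newton–Raphson (separation detected by coefficient divergence); the count
part maximises the zero-truncated NB likelihood with analytic gradients
(L-BFGS on β and ln θ, Poisson-IRLS warm start), standard errors from the
inverse observed information (central differences of the analytic
gradient). The hurdle log-likelihood is the exact sum of the parts;
AIC = 2k − 2logL with k counting both parts plus θ. Zero-inflated
comparators (ZIP/ZINB) maximise the mixture likelihood
P(0) = π + (1−π)f(0) with logit-linear π on the same covariates; ZAP is
the hurdle with a truncated Poisson count part. Pseudo-R² is Nagelkerke
against the matching-family intercept-only model, reported but never used
for selection. Wald p-values mark significance.

Stepwise selection starts from the intercept model and alternates the
best single addition with the best single deletion until neither lowers
AIC; ties break on canonical term order, so the path is deterministic.
No marginality constraint is imposed (quadratic and interaction terms may
enter without their parents), matching how the terms compete in the
selection. Note the statistical property of plain-AIC stepwise: a pure-
noise term is admitted when its likelihood-ratio statistic exceeds 2,
which happens with probability P(χ²₁ > 2) ≈ 15.7% per term. VIF uses
auxiliary OLS of each standardized main effect on the others,
tolerance = 1/VIF, with 0.5 as the pass threshold; exact collinearity is
a named error.

Presence and count parts are selected independently (the two processes —
occupancy and local abundance — need not share drivers).

## Synthetic survey generator

The generator defines the conditions everything is tested under. Latent
monthly density for estuary e:

    latent(e, t) = scale_e · pulse_e(month − lag_e) · exp(f_{t−lag_e} + ε_{e,t})

* `pulse` — raised cosine over the recruitment window (Dec–Mar by
  default), centred two months after its circular midpoint (settled
  recruits peak after settlement, matching the observed March–May density
  peak), width 6 months, floored at 0.15 so off-season density stays
  positive.
* `f` — shared regional forcing: stationary AR(1) on the monthly grid
  (ρ = 0.8, marginal sd 0.55), experienced by each estuary with its phase
  delay (`lag_months`; the northern estuaries default to +1 month). A
  smooth, delayed common driver is what makes a configured lag
  recoverable from detrended cross-correlation; an annual-constant
  forcing would carry no lag information.
* `ε` — independent estuary noise per month (sd 0.8). Both lognormal
  factors are mean-corrected. The shared/noise variance ratio tunes the
  expected portfolio effect; the defaults were chosen once so that local
  peak CVs (~0.5–0.8) and the full-metapopulation CVPE (~1.2–1.4) match
  the magnitudes reported for the real survey.

Per haul: temperature follows a seasonal sinusoid (22 ± 6 °C) with 1.5 °C
noise, salinity N(28, 5²), depth U(0.1, 1.8) m, SAV a categorical draw
over deciles, shore distance U(0, 40) m. Presence is Bernoulli on a logit
scale driven by standardized covariates plus 0.8·ln(latent/scale); given
presence, the count is zero-truncated NB (θ = 1.5 by default) with
log-mean ln(latent·area/100) plus covariate effects (SAV +0.5,
temperature −0.3, salinity +0.2, depth +0.1 per generator-sd).
`min(10, count)` lengths are drawn from the active cohort
(L₀ = 14 mm, G = 0.16/month, sd 6 mm); December mixes new recruits
(fraction 0.5) with the 12-month-old cohort, making December bimodal.
Default long-term density scales are 23 (AB), 6.4 (CK), 40 (TB) and
77 (CH) fish/100 m², the reported long-term means.

What the generator does *not* emulate: spatial autocorrelation within
estuaries, gear selectivity beyond the 10-length subsample, mortality and
egress schedules (lengths are drawn from the cohort mean curve directly),
and habitat–season interactions. Passing recovery tests therefore shows
the estimators are correct under the stated statistical structure, not
that the structure captures every feature of field data.

## Problem sizes used by the checks

The test suite verifies recovery at the survey's own scale where that is
cheap (19 years × 9–20 hauls/month), and at reduced replicate counts
otherwise: growth recovery uses 100 single-estuary replicate surveys at
default effort; hurdle coefficient recovery one survey of ~10⁴ hauls;
stepwise calibration 100 replicates of ~5,000 hauls (presence part);
model comparison 100 replicates of ~5,000 hauls in a sparse,
reliably-present regime (density scale 1.8 fish/100 m², presence
intercept 2.0) where the hurdle's zero-deflation is structurally
unmatchable by a zero-inflated mixture — in high-density regimes ZINB
reproduces the hurdle fit almost exactly and the AIC winner is
uninformative; synchrony lag recovery 200 replicates under a
shared-forcing-dominant configuration (shared sd 0.6, ρ 0.7, noise sd
0.1, θ = 3) and the type-I check 150 replicates × 6 independent pairs;
pipeline determinism two 2-estuary, 5-year runs.

## Known limitations

* The dip's candidate-mode scan is worst-case O(m²) in the number of
  distinct values; the Monte Carlo null multiplies that by B, hence the
  subsampled p-value in the cohort gate.
* Zero-inflated fits use numeric-gradient quasi-Newton from a
  deterministic warm start; pathological designs could converge to local
  optima (the comparison tests guard the regimes used here).
* The white-noise significance bound for synchrony ignores serial
  dependence remaining after detrending; strongly autocorrelated
  anomalies would make it anticonservative.
* Design-based (stratum-weighted) abundance estimation is out of scope;
  monthly means average hauls directly.
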