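# Methods

This note documents the statistical machinery behind `trapdiel`: what each
stage assumes, the constants that govern it, and the choices made where more
than one defensible convention exists. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The diel circle

Detection times are treated as angles on the unit circle,
`theta = 2*pi * (minutes since midnight) / 1440`. All timestamps are local
clock time at minute resolution; no timezone or sun-time transformation is
applied, because the solar bands are themselves defined from monthly *mean*
clock times of sunrise and sunset, and the tropical survey window the
package emulates shows only a few minutes of solar drift per month.

## Temporal independence

Consecutive records of the same species at the same camera are correlated
(an animal lingering in front of a lens produces bursts). The filter keeps a
record iff it falls at least one hour (configurable) after the **last
retained** record of its (site, species) stream; the first record of every
stream is always kept. Measuring from the last retained record — rather
than the previous raw record — is the standard camera-trap convention and
is conservative: a long burst collapses to one record per hour regardless
of its internal spacing. The filter is idempotent and returns a subsequence
of its input; it never deduplicates on behalf of the reader.

## Solar time bands and electivity

Each calendar month carries a mean sunrise and sunset. Four bands partition
the 24-h cycle with half-open `[start, end)` intervals:

* **Sunrise**: `[sunrise-1h, sunrise+1h)`
* **Sunset**: `[sunset-1h, sunset+1h)`
* **Day**: `[sunrise+1h, sunset-1h)`
* **Night**: the remainder.

Verbal definitions of these bands ("day is between sunrise and sunset")
overlap with the crepuscular hours; the package gives the crepuscular bands
precedence so that the partition is exact and testable. Availability is
`p_Sunrise = p_Sunset = 2/24` per month, `p_Day` the daylight span minus the
two crepuscular hours, `p_Night` the rest; monthly availabilities are
averaged with weights defaulting to the sample's detections per month (so
`p` matches survey exposure), with uniform weighting behind a flag. A day
shorter than the two crepuscular hours is rejected as degenerate.

Selection of a band compares use `r` (proportion of independent detections
in the band) with availability `p` through Jacobs' index

    D = (r - p) / (r + p - 2 r p),

bounded on [-1, 1]. Uncertainty comes from resampling the detections with
replacement (equivalently, a multinomial draw over observed band counts) and
recomputing `D`; the bootstrap mean and a percentile interval are reported
alongside the plug-in value, since published tables in this field do not
always say which of the two they print.

Species with enough detections (> 40 by default) can be classified from
their own daylight proportion `q` (sunrise-to-sunset window, crepuscular
halves included by default): nocturnal below 0.10, mostly nocturnal to
0.30, cathemeral to 0.70, mostly diurnal to 0.90, diurnal above. The break
values are configuration, not dogma; rarer species keep their trait-table
(literature) label.

## Kernel density estimation

The activity density is a von Mises kernel estimate,
`fhat(t) = (1/n) sum_i vM(t; t_i, kappa_kernel)`. The kernel concentration
follows the plug-in bandwidth rule of the overlap-estimation literature:
with `kappa_hat` the sample's maximum-likelihood von Mises concentration
(capped at 3 so multimodal samples are not over-sharpened),

    kappa_kernel = [3 n kappa_hat^2 I2(2 kappa_hat)
                    / (4 sqrt(pi) I1(kappa_hat)^2)]^(2/5),

multiplied by an adjust factor: 0.8 when the density feeds the grid-based
overlap estimator and 1.0 for the point-based one (the small-sample
recommendation of that literature). The gridded density (128 points by
default) is renormalised so its trapezoidal integral over the circle is
exactly one, and off-grid evaluations apply the same factor. A sample of
identical angles falls back to the maximum supported concentration with a
warning. The ML concentration itself is obtained by Newton iteration on
`A1(kappa) = I1/I0 = Rbar` from Fisher's piecewise starting value,
vectorised for the bootstrap.

## Watson U² tests

One-sample uniformity uses
`U² = sum_i (u_(i) - (2i-1)/(2n))² - n(ubar - 1/2)² + 1/(12n)` on
`u = theta/2pi`. The reported statistic is unmodified (an equispaced
configuration gives exactly `1/(12n)`); the p-value applies the Stephens
finite-sample modification `(U² - 0.1/n + 0.1/n²)(1 + 0.8/n)` before the
asymptotic series `P(U² > x) = 2 sum_m (-1)^(m-1) exp(-2 m² pi² x)`. Tests
need `n >= 8`; the per-species uniformity flag is reported at
`alpha = 0.001`.

The two-sample statistic is `U² = nm/N² * sum_k w_k (d_k - dbar)²` where
`d_k` is the difference of the two empirical CDFs over the pooled sorted
sample. Ties are handled by evaluating `d` once per distinct pooled value
with tie-multiplicity weights `w_k`, which removes any dependence on the
arbitrary ordering of tied observations (identical samples give exactly
zero); a seeded-jitter option exists for exactness checks against
tie-free references. The p-value applies the same Stephens-type correction
with `N = n + m`; empirical type-I error at `n = m = 50` is checked at
5% ± 1% in the test suite. Two-sample comparisons in the tourism report
use `alpha = 0.05`.

## Overlap coefficients

The overlap of densities `f` and `g` is `Delta = int min(f, g)`. Two
estimators:

* **Dhat1** (grid): trapezoidal integral of `min(fhat, ghat)` over the
  shared grid — used when the smaller sample has fewer than 75 detections.
* **Dhat4** (points): `0.5 * [mean_i min(1, g(a_i)/f(a_i)) +
  mean_j min(1, f(b_j)/g(b_j))]` — used otherwise. The boundary case
  `n = 75` takes Dhat4, because the small-sample rule is stated strictly
  ("below 75"). Points where both densities are numerically zero
  (< 1e-12) contribute a ratio of one, with a warning.

Confidence intervals come from a smoothed bootstrap: each replicate
resamples both sets of source angles with replacement, perturbs every angle
by von Mises noise at the fitted kernel concentration (equivalently, draws
from the fitted density), re-fits both densities — including their
bandwidths — and recomputes the selected estimator. Because replicates are
drawn from an already-smoothed density, their distribution is centred above
the plug-in estimate; the default interval therefore recentres the
percentile interval on the estimate (the flavour the reference methodology
recommends). The raw percentile and a bias-corrected percentile interval
remain available as options. Dedicated simulations in the acceptance suite
check 95% coverage within ±3 points at n = 100 per side.

Overlap classification is deliberately self-referential, as in the source
methodology: the 50th and 75th percentiles (linear interpolation) of the
delta values *within the analysed comparison set* split low
(`Delta <= P50`), moderate, and high (`Delta > P75`). A fixed-threshold
mode is available for cross-study comparability; a single comparison is
left unclassified with a warning.

## Species accumulation

The sampling unit is the camera-trap-day (site-level and detection-level
units behind a flag). Units are shuffled 1000 times; the mean cumulative
species count and a percentile band form the curve, whose exact expectation
`E[S_k] = sum_j (1 - C(N-n_j, k)/C(N, k))` serves as an independent oracle
in the tests (computed in log-gamma space). Every permutation ends at the
observed richness, and the mean curve is non-decreasing.

## The tourism comparison

`TourismStudy.fit` chains: independence filter → analysis units → calendar
split → per-unit overlap + CI + two-sample test → percentile
classification. Units are (i) each species above the abundance threshold,
(ii) the whole community, (iii) diel guilds — nocturnal pools nocturnal and
mostly nocturnal species, diurnal pools diurnal and mostly diurnal;
cathemeral species belong to the community and trophic units but no guild —
and (iv) trophic groups, where any group under 40 independent detections is
pooled into its neighbour (carnivores into omnivores first). A unit whose
smaller class falls below 8 detections (the Watson precondition) is
reported as skipped rather than failed. The report carries the seed and a
configuration hash, and fitting never mutates its inputs, so a fixed seed
reproduces the report byte for byte.

## The synthetic generator

Each simulated species has a von Mises mixture activity density, a Poisson
detection rate per site-day (negative-binomial overdispersion is out of
scope), and optional tourist-day effects: a phase shift of the mixture
and/or a rate multiplier. The default design mirrors the emulated study:
six cameras, 102 consecutive days, 52 tourist days, tropical dry-season
solar times (a constructed stand-in table, not an ephemeris). Default
per-species rates were set once so independent detections land near the
published per-species counts (about 200 for the most abundant species down
to a handful for the rarest). The truth manifest records every parameter
plus the analytic overlap between the tourist and baseline regimes,
computed by 4096-point quadrature of `min` of the two mixture densities.

What the generator does *not* emulate — and hence what passing tests cannot
show about real surveys: detection probability varying with distance,
habitat or temperature; inter-species attraction/avoidance; serial
correlation beyond optional fixed-spacing bursts; camera downtime (the
synthetic effort is a full 612 trap-days, where a real survey lost days to
battery and card changes); and observation error in species identification.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerance they assert: 10,000 replicates for test
calibration at n = 50; 500 data sets × 500 bootstrap replicates for CI
coverage at n = 100 per side; 20 pipeline replicates for the end-to-end
null and power checks; 1000 permutations against the exact accumulation
expectation on a 30 × 10 incidence matrix. Kernel densities default to a
128-point grid (the integral of a normalised density is exact to well below
1e-3 there); analytic overlap uses 4096-point quadrature, checked against a
doubled resolution. Bootstrap kernels cap concentration at 700, beyond
which a von Mises is numerically a point mass.

## Known limitations

* Published per-species electivity and overlap values cannot be recomputed:
  the underlying raw detections were never deposited. The packaged tables
  are inputs for arithmetic cross-checks only.
* The percentile classification of overlap depends on the comparison set;
  adding a unit can relabel the others. This mirrors the source
  methodology and is the default on purpose.
* Two-sample Watson p-values rely on an asymptotic series; below about
  eight detections per class they are unreliable, which is why such units
  are skipped.
* The activity-cycle break points (0.10/0.30/0.70/0.90 daylight
  proportion) are a configurable convention for the cited classification,
  which the source does not restate.
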