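# Methods

## The stay-at-home measure

The measure starts from gridded mobile-location counts: for each 500 m
mesh element and demographic cell (prefecture × age group × gender), a
daily *nighttime population* (mean head count over 00:00–05:00) and
*daytime population* (mean over 09:00–17:00). Construction is in three
steps.

1. **Residential detection.** Over a pre-pandemic baseline window
   (defaults: January 6–31, 2020), a mesh is residential if its mean
   daytime population is *strictly* smaller than a threshold θ (default
   0.8, sensitivity 0.7/0.9) times its mean nighttime population. The
   mask is computed once from the baseline, not day by day, so that the
   set of "home" areas is stable; a mesh with zero nighttime population
   can never be residential. Detection is per demographic cell by
   default (a pooled variant is available) — the feed reports counts per
   cell, and residential structure can differ by age and gender.
2. **Leaver counting.** Within residential meshes, daily home-leavers are
   nighttime minus daytime population, summed over meshes. Negative
   per-mesh values (a mesh gaining daytime population) are retained, not
   floored, so that aggregation is exact; a documented switch floors
   them. Missing mesh-days count as absent (no imputation) and are
   logged.
3. **Baseline deviation.** `y = −100 · (L_t − L̄) / L̄` with `L̄` the
   cell's baseline mean of daily leavers. Positive y = more staying home.
   By construction y averages to zero over the baseline in every cell; a
   cell whose baseline mean is not strictly positive is rejected with a
   message naming it.

Prefecture-level series are phone-owner-weighted means across the
fourteen age×gender cells.

## Covariates

Daily new infections and deaths per prefecture are smoothed with a
*trailing* 7-day moving average (people react to the weekly trend, not
daily prints, which have strong day-of-week artifacts), then transformed
with `arcsinh(x) = ln(x + √(x²+1))`. The order — average first, then
transform — keeps all-zero weeks exactly at zero and preserves the trend
interpretation; the first six days use the available prefix (inert at
defaults, where baseline weeks are all zero; a drop-instead switch
exists).

Policy dummies come from interval calendars: a state of emergency is
active from the day *after* its declaration through the lifting day
inclusive; a school closure from the closure date through the day before
reopening. Brief reopenings (gap ≤ g days, configurable) are merged. The
rain dummy is a prepared 0/1 column (precipitation > 0 at the
prefectural capital). Saturdays, Sundays and the national holidays in
the shipped (editable) 2020 calendar form the weekend/holiday sample;
the 315-day study window splits 211/104.

Region membership ships as an editable 7-region fixture (the common
grouping that merges Hokkaido with Tohoku and Kyushu with Okinawa).

## Estimator

Weighted least squares with phone-owner weights; prefecture (or cell)
and day×region fixed effects absorbed by weighted alternating
projections (iterated group demeaning, tolerance 1e-12), which converges
to the exact weighted projection — coefficients agree with an explicit
dummy-variable solve to ~1e-10 and the estimator scales to designs with
thousands of absorbed levels. The absorbed degrees of freedom use the
exact two-factor rank L₁ + L₂ − C, with C the number of connected
components of the bipartite level graph (union-find). Adjusted R² is
computed on the untransformed dependent variable, i.e. including the
absorbed effects, matching how such panel tables are conventionally
reported.

**Inference.** Default covariance is the CR1 cluster sandwich — meat
summed over prefecture score blocks, finite-sample factor
G/(G−1)·(N−1)/(N−K) with K counting absorbed effects — the convention
behind the reported standard errors and significance stars (stars from
normal quantiles at 10/5/1%). Confidence intervals use t(G−1) critical
values. Clustering is at the prefecture level because treatment varies
at that level; the cluster factor is configurable.

CR1 is known to be biased downward when only a handful of clusters carry
the identifying variation. That regime is real here: emergency-timing
variation comes from a minority of early-adopter and late-lifting
prefectures, and in reduced 12-prefecture simulations CR1 intervals for
the emergency effect cover only ~87% instead of 95% even with exactly
homoskedastic noise, while the same estimator covers 92–96% at 47
prefectures. The package therefore also provides the leave-one-cluster-
out jackknife (CV3, `fit(..., vcov="cr3")`), the standard few-cluster
remedy, and uses it for interval-based calibration studies; its
simulated coverage at the reduced size is 93–97%.

**Time-varying coefficients.** The infection (and optionally death)
response is interacted with day dummies — identified per date from
cross-prefecture variation within regions. Dates without such variation
(e.g. the all-zero baseline) are flagged as unidentified and reported as
NaN, never as silent zeros. Displayed paths are centered 11-day moving
averages with shrinking windows at the edges; decompositions always use
the raw per-date coefficients so the accounting identity is exact.
ISO-week interaction bins produce the weekly coefficient tables consumed
by the second stage.

## Decomposition

Each fitted row splits exactly into: intervention (school + emergency
contributions), information (infections + deaths + recovered time
effects), the rain control ("other"), the cell fixed effect, and the
residual. The absorbed component is separated into cell and time parts
by alternating weighted means; the split is only identified up to
constants within connected components, so the time effect is normalized
to zero weighted mean over the baseline window within each region (the
"deviation from normal times" reading) and the constant moves into the
cell effect. Single-prefecture series use that prefecture's own region
path; national series weight-average across cells. Weekday filtering is
the default reporting convention (weekend seasonality is large).

## Second stage

`arcsinh(β₁a)` is regressed on `arcsinh(θ_a)` — arcsinh rather than log
because estimated coefficients can be negative — giving the elasticity η
in the large-value regime; the construction `β_a = sinh(k·arcsinh θ_a +
c)` is inverted exactly, which the tests exploit. The 15–19 group is
excluded by default (their outings mostly reflect parental and school
decisions). A log10 variant is offered for the per-decade reading; which
scale a given published figure used can be ambiguous, so neither is
asserted as canonical. Severity rates come per observation period
(Jan–Apr, Jun–Aug) with the published imputation conventions: May is the
mean of the two periods, September onward carries Jun–Aug forward.

The weekly variant pools gender × age × week points with week dummies,
arcsinh(θ)×week interactions and a women dummy. Robust standard errors
are HC3: per-week subsamples have ~12 points, where HC1 error bands
cover only ~79% of a nominal 90% in simulation versus ~87% for HC3 —
the standard small-sample recommendation. Error bands are estimate
± 1.645 × robust SE. First-stage estimates enter as data (no
errors-in-variables correction) — a known limitation shared with the
study design this mirrors.

## Synthetic worlds

The generator emulates the study conditions: 47 prefectures in 7 regions
over a 315-day calendar (Jan 6 – Nov 15) with a January 6–31 baseline;
scaled-down variants shrink the panel but keep the *absolute* day gaps
between policy events (declarations 9 days apart; liftings +7/+11 days
after the first batch; school reopening spread over ~8 weeks) and the
historical adoption proportions (7/47 early adopters; 39/3/5 lifting
batches, later batches never empty). Epidemics are Poisson draws around
three Gaussian waves with lognormal prefecture scales (σ = 1.2, so a few
prefectures dominate counts and most death cells are zero, as in the
real data); deaths are Poisson with a 14-day lag and 2% fatality. Rain
is Bernoulli(0.3) per prefecture-day. Phone-owner weights are lognormal
across cells — the true joint distribution of phone ownership is not
public, so this is a stand-in. Severity tables are synthetic stand-ins
with the ~150× old/young severe-illness ratio.

The hidden behavior layer is built from the *same transformed covariates
the pipeline constructs* and then centered per cell over the baseline,
so the mesh-derived measure reproduces it exactly at zero noise; it is
clipped to (−100, 100) pp with the clip count reported (never triggered
at defaults). Residential meshes send out 50% of their nighttime
population in normal times — guaranteeing the detector's premise
(0.5 < 0.8) — and daily leavers scale as `L̄·(1 − y*/100)`; each cell
also gets decoy meshes with daytime > nighttime to exercise the
detector. Optional Poisson count noise on mesh populations produces
measurement error that shrinks with cell population. Default behavioral
noise is σ = 2 pp, which reproduces the ~0.95 adjusted R² regime of
prefecture-level fits.

What the generator does **not** emulate: feedback from behavior to
infections (no SIR coupling), within-prefecture geography, reporting-day
artifacts, or serially correlated behavioral shocks. Passing tests
therefore validate the pipeline's algebra, identification logic and
calibration under the stated conditions — not the substantive magnitudes
one would obtain on the proprietary data.

## Problem sizes used in checks

Round-trip and identity checks run on 6-prefecture, 86-day worlds with
three residential meshes per cell; calibration studies use 200 worlds of
12 prefectures × 150 days (single demographic cell) and one full-size
47 × 315 world for rank recovery and the aggregate fit; the weekly
second-stage study uses 50 replicates of 20 weeks. These sizes give
stable Monte Carlo rates while keeping the whole suite fast.

## Known limitations

- CR1 few-cluster bias is mitigated (CV3), not eliminated; wild cluster
  bootstrap is not implemented.
- Difference paths between age groups use the independent-fit SE
  approximation (fits share no observations but do share calendars).
- The per-cell residential mask convention is a choice; the pooled
  variant is available but the published construction does not say which
  was used.
- Policy calendars support one merged interval sequence per prefecture
  and policy; overlapping intervals of the same policy are merged, not
  rejected.
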