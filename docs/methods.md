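# Methods

`phenoshift` re-implements, as a tested pipeline, a community-level analysis
of decadal change in flowering phenology: circular-statistical phenometrics
from weekly flower counts, climate trend models, co-flowering reassembly
bookkeeping, and the phylogenetic signal of phenological change. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic data do and do not establish.

## Dates on a circle

Flowering recurs annually, so calendar dates are treated as angles:
day-of-year *d* maps to *d*·360/365 degrees, and Feb 29 is collapsed onto
day 59 so every year shares one 365-day circle. Pooling censuses from
several years onto one circle is what lets two multi-year observation
windows ("decades") be compared as two circular samples.

A date sample is summarised by its mean angle μ (direction of the vector
sum) and mean resultant length r ∈ [0, 1]; r near 1 means strong
seasonality. The von Mises concentration κ is estimated by inverting
A₁(κ) = I₁(κ)/I₀(κ) = r, starting from Fisher's piecewise approximation and
polishing with Newton steps on the exponentially scaled Bessel ratio to a
1e−10 tolerance. When r is numerically zero (below 1e−12; e.g. an antipodal
pair) the mean direction does not exist: the summary carries an explicit
`defined=False` flag and μ = nan, and downstream consumers must check the
flag — undefined means are never silently propagated.

Signed shifts between two mean dates take the shortest arc and are reported
in days with **positive = advance** (the new date is earlier). The same
convention makes a positive duration delta a lengthening. Every output
table states this convention.

## The four hypothesis tests

* **Rayleigh** (seasonality): Z = n r², with the classical series
  approximation for the p-value; a seeded uniform-resampling Monte-Carlo
  mode exists for n < 10, where the series is not trustworthy.
* **Watson–Williams F** (equality of two mean directions): the standard F
  statistic with the 1 + 3/(8κ̂) concentration correction, κ̂ estimated from
  the within-group mean resultant length. The correction assumes
  concentrated data; below r̄ = 0.45 a warning (not an error) is issued.
* **Equal-kappa** (equality of concentration): the classical piecewise
  scheme keyed on the pooled r̄ — arcsine variance-stabilisation for diffuse
  data (r̄ < 0.45), arcsinh in the mid range, and a Bartlett-type statistic
  at high concentration (r̄ > 0.70) — referred to χ²(1). Calibration was
  verified by simulation (rejection ≈ 5% at α = 0.05 under the null). Note
  that at small n the asymptotic p tracks a *parametric* Monte-Carlo
  reference closely but differs from a conditional label-permutation p by
  a few hundredths; this is inherent to conditional vs unconditional
  dispersion inference, not a defect of the approximation.
* **Circular rank test** (peak-date location, no von Mises assumption): the
  pooled sample is re-origined at its circular median, angles are ranked
  along the circle, and the Wilcoxon rank-sum statistic is referred to its
  seeded label-permutation distribution (two-sided, +1 correction,
  n_perm ≥ 999). The original analysis cited a simulation-based circular
  "Wilcoxon test" without an algorithm; this permutation rank-sum is the
  documented reconstruction, and it agrees with exact rank-sum enumeration
  on the same circular ranks.

## From counts to phenometrics

A flowering season of one individual is a maximal run of censuses with
positive counts; runs separated by fewer than 3 consecutive zero censuses
are merged (a single empty mid-season census does not split a season), and
when several distinct seasons fall in one window the longest is used. Start
= first positive census, end = last, peak = census with the maximum count
(ties break to the earliest — deterministic), duration = end − start in
days (not +1; applied consistently, so only cross-decade differences
matter). Seasons spanning New Year are handled by construction because real
calendar dates are differenced before reduction to day-of-year.

Species-by-decade pooling: circular means (and circular SDs, √(−2 ln r),
reported in days) of starts and ends; the species peak is the circular
median of the individuals' peak dates, with the pooled-production
alternative (`pooled_production_peak`: the day whose summed count across
individuals is highest) available; arithmetic mean duration. Decade
contrasts per species: Watson–Williams on start and end dates, the circular
rank test on peaks, one-way ANOVA on durations (for two groups this F is
exactly the squared two-sample t). α = 0.05 per species, no
multiple-testing correction — matching per-species reporting conventions in
community phenology; the α is a parameter.

Each species is then classified by the significance and direction of its
start and end shifts into one of eight patterns (full advance, start-only
advance, end-only advance, no change, start delay with end unchanged, start
delay with end advance, full delay, other); the classification is a pure
function of the four test outcomes.

The community flowering curve counts, for each day of year, the species
whose mean-start→mean-end arc covers it. The community-level mean-date
contrast uses these per-day species counts as integer weights (each day
enters as many times as it has species in flower); a per-species-dates mode
exists, and the mode used is recorded in the test result.

## Co-flowering reassembly

Species decade intervals are the rounded mean start→end arcs (per-individual
union mode is out of scope). Day counting is inclusive: flowering on days
10..20 is 11 flowering days, for numerator and denominator alike, so the
overlap proportion of a focal species f with another o is
shared_days/days(f). The matrix is asymmetric but satisfies the exact
integer reciprocity identity entry(f,o)·days(f) = entry(o,f)·days(o).

The decade-change matrix divides the later proportion by the earlier one:
ratios ≥ 1 are reported as-is (0.2 → 0.4 gives 2), decreases are reported
as −ρ (0.4 → 0.2 gives −0.5); the alternative −1/ρ encoding is a
configuration switch. Pairs overlapping only in the later decade are
GAIN, only in the earlier LOSS, in neither NONE. "Unchanged" means a fold
of exactly 1 in integer-day arithmetic — no tolerance band, configurable.
Category counts treat gains as increases and losses as decreases
("increased, including the gain of ..." bookkeeping).

For pollinator-mediated interaction potential, the change matrix is reduced
to ternary values (+1 increase, −1 decrease, 0 otherwise) and masked to
species pairs that are both insect-pollinated and share at least one main
pollinator agent. Guild phrases are tokenized into atomic agents (small /
medium / big bees, hoverflies, beeflies, flies, very small flies,
butterflies, sphingids, wasps, beetles); "small to big bees" expands to all
three bee sizes and "Lepidoptera" to butterflies + sphingids. This
granularity lets a species whose only agent token is shared by no one drop
out of the competitor analysis naturally, while wind-pollinated species are
excluded outright. Per-species net sums, their total, and mean ± sd over
included species summarise the reassembly.

Rank order: species are ranked by mean start date within each decade
(rank 1 = earliest, the year anchored at day 1; ties alphabetical) and the
rank difference is reported.

## Climate trends

Nearby stations are averaged per date (unweighted over the stations
reporting) to minimise gaps. Aggregates are annual or meteorological-season
values — temperature means, precipitation sums — with December assigned to
the winter labelled by the following January's year. An aggregate requires
≥ 80% of its days observed, else it is missing; the threshold guards
against biased seasonal means and is a module constant. Trends are OLS of
the aggregate on calendar year with a two-sided slope p; fitting on
aggregates is the primary model (a daily-resolution fit is a trivial
variant the caller can run on the daily series). The cross-species
regression of duration change on start-date shift is the same OLS
machinery.

## Pagel's λ

Under Brownian motion the tip trait vector is MVN with covariance σ²V,
V(i,j) = shared root-to-MRCA path length. λ multiplies the off-diagonal of
V. For each λ the root state and σ² are concentrated out by GLS (ML
divisor n), giving a 1-D profile likelihood over λ ∈ [0, 1], maximised by
bounded Brent searches around a multi-start grid {0, 0.25, 0.5, 0.75, 1}
plus the best point of a 21-point scan — boundary optima at 0 and 1 are
found exactly, and λ = 0 is always in the search set so logL ≥ logL(λ=0)
by construction. Significance is the χ²(1) tail of the likelihood ratio
against λ = 0; because λ̂ can sit on the boundary this is conservative, and
the ½χ²(0) + ½χ²(1) mixture is available by flag. Likelihood values were
verified against direct multivariate-normal density evaluation to 1e−8.

Traits are magnitudes of phenological change. Signed day shifts are made
positive by the monotone shared transform log(x + 1 − min x) before
fitting (raw-scale fitting is available); species present in the trait
table but absent from the tree are dropped with a logged warning, tips
without trait values are an error. The reported λ̂ is the true bounded
optimum — genuinely signal-free traits yield λ̂ = 0 exactly rather than a
small positive floor.

## Synthetic data: what it emulates, what it does not

The generator is a pure function of (spec, seed). Flowering: each
individual's expected open-flower count follows a circular Gaussian bell
(amplitude × exp(−½((d − peak)/spread)²)), with the individual's peak
jittered around the species peak (sd 4 d by default) and integer counts
drawn Poisson — count data with mean-preserving noise and no claimed
overdispersion. Censuses are weekly (7-day default) over two multi-year
windows. A decade-2 start advance s with duration change Δ is injected by
moving the peak to peak − s + Δ/2 and widening the spread by Δ/4, so on the
nominal ±2-spread window the start advances by exactly s and the end by
s − Δ.

The default community has 51 species, ~70% of them peaking between days 60
and 180 (late winter–early summer) and the rest in summer/autumn; 9–21
individuals per species; 80% of species advancing (mean 24 d, clipped to
6–92 d), 6% delaying, the rest static; duration change = 0.5·shift + noise,
so stronger advances lengthen flowering; four wind-pollinated species and
one species with a pollinator token shared with no other. Climate: tmin and
tmax carry their own linear trends (defaults 0.057 and 0.019 °C/yr from
1974 bases of 8.9 and 24.9 °C — minima warming fastest), a shared
sinusoidal annual cycle peaking in late July, Gaussian noise, and
tmean = (tmin + tmax)/2 so the ordering invariant holds by construction;
precipitation is winter-concentrated Bernoulli–exponential rain whose
wet-day scale drifts slowly downward and is modulated by a shared lognormal
year factor (log-sd 0.35) emulating the large interannual variability of
Mediterranean rainfall. Three stations share the signal with small constant
offsets, independent noise, and 5% independent missingness. The tree is a
pure-birth (Yule) process rescaled to unit height.

Known divergences from real data, hence limits of what passing tests show:
detected starts and ends are census-grid- and detection-limited (a bell
tail is "flowering" only once a count is positive), so absolute durations
are biased relative to the nominal ±2-spread truth and duration-change
magnitudes are amplified by roughly the ratio of the detection half-width
to 2 spreads — translations (start shifts) are recovered unbiasedly, which
is why shift-recovery tests use pure translations and the duration–shift
test asserts sign and significance, not magnitude. The generator has no
weather-driven flowering mechanism, no interannual phenological
variability beyond individual jitter, no observation error in counts
beyond Poisson, and pollinator guilds are labels, not visitation data.

## Problem sizes and numerical conventions

Stochastic test suites use: 100-sample batches for oracle agreement of the
asymptotic p-values (batch-mean |Δp| ≤ 0.01); 500 replicates for type-I
calibration (5% ± 2%); 100 replicates for the 20-day shift recovery
(±7 days, one census interval, ≥ 90%); 60 replicates for the
duration–shift slope and climate-slope recoveries (≥ 95% within bounds);
1000 random interval sets for the overlap reciprocity identity; 100
replicates on a 100-tip tree for λ recovery. These sizes keep the default
suite at a few minutes on one CPU while leaving binomial slack well inside
the asserted bands.

Ties: peak ties break earliest; rank ties alphabetical; the circular median
is the smallest minimiser among observed angles. Matrices are written as
labelled CSV at 12-decimal fixed format and round-trip exactly at that
precision; change-matrix cells render GAIN/LOSS as the sentinel strings
"gain"/"loss".
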