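# Methods

This note documents the models, the defaults and the design choices
behind each estimator, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## River geometry

A river reach is a 1-D axis of official kilometer posts increasing
downstream, from `km_start` to `km_end`, plus optional side branches
treated as additive 1-D segments with their own axes. The habitat strip
assumed to hold living mussels is a constant-width band (default 20 m)
along each bank — mussels concentrate in the slow-current coastal zone
and between spur dikes — so river-scale area is simply
length × width × number of banks. Spur-dike fields may widen or narrow
the effective strip locally; a constant width is assumed because no
field measurement of local variation is available.

## Carcass flux

Sessions of m minutes yield counts xᵢ of carcasses crossing the
observation line. The corrected per-minute rate is
((1/n)Σxᵢ/ω)/m, where ω ∈ (0, 1] is the average probability that a
drifting carcass is seen. ω is treated as a fixed known scalar
(default 0.6, a literature strip-transect detectability); its
uncertainty is explored by an explicit sensitivity sweep
(`omega_sensitivity`) rather than being propagated into the CI. Daily
extrapolation multiplies by 1440 minutes, which assumes flux
stationarity over the day — sessions taken at 2-hour intervals are
treated as exchangeable draws. Mixed session lengths are supported by
averaging per-session per-minute rates; for equal lengths this reduces
to the verbatim formula, bit for bit.

The 95% CI is a percentile bootstrap over sessions (default 10,000
resamples, seeded). A session-resampling bootstrap was chosen because
the session count is small and no distributional form for the counts is
assumed; at n = 12 sessions its empirical coverage is about 91–93%,
the usual mild undercoverage of the percentile method at small n.

## Shore-deposited totals

Counts on 10-m bank transects are modelled as Poisson with a log link
and a cubic B-spline smooth of river kilometer (default basis dimension
10, second-order difference penalty). The smoothing parameter is chosen
by generalized cross-validation, minimizing n·D(λ)/(n − edf(λ))² over a
log-spaced grid (λ ∈ 10⁻²…10⁷), with D the deviance and edf the
hat-matrix trace of the penalized IRLS fit. Transect site enters as a
categorical term when at least one site contributes repeated
observations; with one observation per site the term is unidentifiable
and is dropped. Predictions for unnamed sites marginalize over the
observed site effects with frequency weights. Exactly constant counts
are short-circuited to a flat smooth (they are their own exact
penalized fit, which the IRLS solver otherwise flags as perfect
separation).

The average rate of change across successive river sections (default
1 km) is a Poisson log-link marginal regression of count on section
index solved by generalized estimating equations, exchangeable working
correlation within site clusters, sandwich variance. Exchangeable is
the standard default for repeated spatial clusters; with independent
clusters the point estimate coincides with the independence solution.

Extrapolation is x̂ = n_banks · (L_m/ℓ_m) · x̄ with L the assessed
length and ℓ the transect length: the printed two-bank form x̂ = 2Lx̄
is dimensionally consistent only when L is counted in transect units,
which is how it is implemented. The bank factor is exposed rather than
hard-coded so single-bank surveys extrapolate correctly.

`estimate_shore_total` averages smooth predictions over 1-km section
midpoints and extrapolates; its CI bootstraps the raw per-transect mean
(extrapolation is linear in the mean, and under uniform random
placement the sample mean is the design-unbiased estimator that the
smooth refines). Refitting the smooth inside every bootstrap resample
would multiply cost by the resample count for little change in the
interval.

The IDW surface retains only positive values, log₁₀-transforms them,
and weights by d^(−power) (default power 2). Nodes coincident with data
points take the data value exactly; all interpolated values are convex
combinations of the input log values and therefore bounded by their
range. No log(x+1) adjustment is applied — zeros are excluded, not
shifted. Output formats are a GeoJSON point lattice and an ESRI ASCII
raster; no CRS handling or cartography is attempted.

## Population differencing

Sample densities are standardized per sample (count/area) and then
averaged — not pooled-count over pooled-area — because samples are the
survey's replication unit; the pooled alternative is available via
`pooled=True`. Diving and net samples are weighted equally. River-scale
abundance is density × strip area; mortality is the before − after
difference, with percent decline kept at full precision internally and
rounded only at reporting time (two significant figures). With the
printed Odra inputs the pipeline yields 66.0 M dead and an 87.3%
decline; the published headline (≈65 M, 88%) reflects rounding applied
upstream of the printed densities.

The before/after test is gated on normality: Shapiro–Wilk on each group
at α = 0.05, ANOVA when **both** pass (the conservative conjunction),
Kruskal–Wallis otherwise. A constant group fails the gate by
definition; two constant groups produce a degenerate-variance warning
and no statistic. Histogram bin counts and Q-Q point coordinates are
emitted as data for external plotting.

## Photo co-mortality

The estimator is a ratio of means: (mean target count per photo) /
(mean reference count per photo), scaled by an independent estimate of
the reference total. Ratio-of-means was chosen over mean-of-ratios
because the latter is undefined for photos without reference
individuals; such photos are kept in both means by default (dropping
them, available as an option, biases the ratio upward). Appending a
photo empty of both taxa rescales numerator and denominator by the same
photo count and leaves the ratio unchanged; appending a photo with only
reference individuals lowers it — the estimator is sensitive to the
composition of the photo sample, not just its size. Counting obeys the
annotation's exclusion mask: labels may exist in excluded cells (the
annotation records everything) but never contribute to counts. No
image processing is performed; annotations are the input.

## Vertebrate biomass

Fish mass uses W = a·Lᵇ with species-specific coefficients (a > 0, b
warned outside [2.5, 3.5]). Mean individual mass is the mean of
per-individual masses, not the mass of the mean length — Jensen's
inequality makes a·(mean L)ᵇ an underestimate for b > 1. Lengths are
pooled per taxon across the dataset; a fish taxon with no lengths
anywhere requires a config-supplied fallback mean mass. Non-fish
vertebrates are tallied and extrapolated as counts only. The shipped
coefficient table is synthetic and illustrative; real analyses must
supply coefficients from an authoritative converter. Extrapolation
delegates to the shore machinery, typically reported for both a
lower-river reach and the full affected length. Habitat screening is
Kruskal–Wallis on per-transect counts (statistic 0, p 1 when every
transect is identical) plus the shared abundance smooth.

## Synthetic-data generator

The generator's defaults encode the study conditions of the 2022 Odra
surveys: ω = 0.6; a true flux of 10 carcasses/min (5-minute counts of
around thirty, the magnitude of the observed sessions); 12 transects +
56 random points for the shore survey, both treated as 10-m units; 13
benthic samples per period with areas near 3.5 m² (46 m²/13 points);
densities 12.6 ind/m² before and a decline fraction of 0.873 (the value
the printed densities imply); 13 photos with a 2.26 snail:mussel
composition (the 147 M : 65 M headline proportion); 43 vertebrate
transects over a 20-km reach. Shore counts are negative binomial
(dispersion k = 2) around a smooth spatial trend — carcass deposition
is aggregated, and Poisson counts would make coverage tests
unrealistically easy. The deposited total is spread over the full
assessed axis including branches, with branch segments continuing the
km axis and the trend clamped at its last control point. A scenario
seed expands into fixed per-generator substreams, so adding a generator
never perturbs existing draws, and every generator is byte-reproducible
given (config, seed). The true flux of 10/min and the shore total of
500,000 are round working values — the field survey's actual totals are
not printed anywhere and are not needed for recovery testing.

What the simulator does **not** emulate: tides and seiches re-floating
carcasses, decomposition losses between deposition and survey, observer
differences in ω, spatial correlation between nearby transects beyond
the shared trend, and photo perspective distortion (the exclusion mask
is generated directly). Passing recovery tests therefore demonstrates
estimator correctness under the stated sampling models, not robustness
to these field effects.

## Problem sizes and numerical choices

The recovery studies run at the survey design sizes: 1,000 flux
replicates (12 sessions each, 1,000 bootstrap resamples inside the
coverage loop; the user-facing default remains 10,000), 500 shore
replicates of 68 sampling units in the test suite and 200 in the
acceptance script, 100 photos for ratio recovery. GCV grids use 19
log-spaced penalties. Bootstrap percentiles are the 2.5th/97.5th.
JSON serialization rounds floats to 6 significant digits for stable
byte-identical reports; the human-readable report rounds to 2
significant figures.

## Limitations

- The 20-m strip and its constant width are assumptions, not
  measurements; abundance scales linearly in both.
- ω enters as a known constant; misspecification propagates
  multiplicatively into the flux (halving ω doubles the estimate).
- The GEE slope describes a marginal log-linear trend across sections;
  it is not a spatially explicit deposition model.
- Percent declines near the headline values are sensitive to the
  rounding of input densities; full precision is kept internally.
- The drift-origin distance is a straight speed × time product clipped
  to the frame; no hydrodynamic routing is attempted.
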