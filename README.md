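# riverkill

Estimators for quantifying mass mortality events in river ecosystems —
the kind of die-off the lower Odra suffered in the summer of 2022, when
a toxic *Prymnesium parvum* bloom killed tens of millions of Unionidae
mussels, over a hundred million *Viviparus* snails, and millions of
fish. The package is aimed at field ecologists and environmental
agencies who need to turn rapid post-disaster surveys (timed carcass
counts, bank transects, benthic samples, annotated photographs) into
defensible river-scale mortality figures.

## What it computes

**Carcass flux.** Short timed counts of carcasses drifting past an
observation line, corrected for detectability and extrapolated to a day:

    x̄ = [ (1/n Σ xᵢ) / ω ] / m,    flux/day = 1440 · x̄

with session length m (minutes) and average detection rate ω (0.6 by
default, from seabird strip-transect work). 95% CIs come from a
percentile bootstrap over sessions; current speed × elapsed time gives
the upstream drift-origin reach.

**Shore-deposited totals.** Counts on randomly placed 10-m bank
transects are smoothed along river kilometer with a penalized B-spline
Poisson GAM (GCV-selected penalty, site as a categorical term where
identifiable), the average rate of change across successive river
sections is estimated by GEE with an exchangeable working correlation
and sandwich variance, and section predictions are extrapolated with

    x̂ = n_banks · (L / ℓ) · x̄

where L is the assessed river length and ℓ the transect length (the
two-bank form is the familiar x̂ = 2Lx̄ with L in transect units).
Positive predictions can be log₁₀-transformed and interpolated to an
inverse-distance-weighted surface for mapping.

**Population differencing.** Benthic densities standardized to 1 m² and
averaged per period are scaled by the habitat-strip area
(length × 20 m × both banks) to river-scale abundance; mortality is the
before − after difference. The before/after comparison is
normality-gated: Shapiro–Wilk on each group, then one-way ANOVA or
Kruskal–Wallis.

**Photo co-mortality.** Snail losses are estimated proportionally from
grid-annotated shoreline photographs: a ratio of mean snail to mean
mussel counts per photo (cells beyond a demarcation line excluded),
scaled by the independently estimated mussel total.

**Vertebrate biomass.** Species tallies on 10-m transects across all
bank habitats; fish counts convert to mass via W = a·Lᵇ with measured
lengths, then extrapolate with the same transect arithmetic; habitat
effects are screened by Kruskal–Wallis plus the abundance smooth.

A seeded synthetic-disaster simulator generates every input with known
ground truth, so all estimators are testable end to end without field
data.

## Worked example

```sh
riverkill simulate --seed 1 --out demo
riverkill report --inputs demo --out demo_report --seed 1
```

which prints (values rounded to two significant figures):

```
Mass mortality report
=====================
river length assessed      : 1.5e+02 km
habitat strip area         : 6e+06 m^2
carcass flux               : 1.4e+04 ind/day CI (1.3e+04, 1.5e+04)
shore-deposited total      : 4.3e+05 CI (3.2e+05, 5.4e+05)
density before / after     : 13 / 1.7 ind/m^2
abundance before / after   : 7.7e+07 / 1e+07
estimated dead             : 6.7e+07 (86% decline)
before/after test          : kruskal-wallis (p = 1.5e-05)
snail:mussel ratio         : 2
snail total                : 8.7e+05
fish count / biomass       : 1.1e+06 / 99 t
```

The simulated truth here was a daily flux of 14,400 carcasses, a shore
total of 500,000, a density decline from 12.6 to 1.6 ind/m², and a 2.26
snail:mussel composition — each line of the report is the corresponding
estimator recovering those quantities from the generated survey files.
Individual estimators are available as subcommands (`riverkill flux`,
`shore`, `population`, `photos`, `vertebrates`) and as plain library
functions.

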