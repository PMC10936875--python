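# Methods

`scmdecomp` estimates the effect of a community-level shock (the motivating
application is the Flint water crisis and Michigan's school districts) on a
single treated district's educational outcomes, using a demeaned
(intercept-shift) synthetic control fitted jointly to several outcomes, and
decomposes the estimated effects across dichotomous student subgroups.

## The estimator

**Panel.** The unit of analysis is the geographic district-year. Student
records are collapsed to district-year means of four outcomes: math and
reading achievement (standardized within grade-subject-year cells to the
statewide distribution, observed for grades 3–8 from 2007), special-needs
classification (from 2006), and the fraction of school days attended (from
2009). A year label denotes the spring of a school year; with treatment
year 2015, the 2014–15 school year is the first post-treatment
observation. Empty cells are omitted, never imputed; estimators tolerate
missing rows only outside each outcome's availability window.

**Demeaning.** For each outcome, every unit's pretreatment mean is
subtracted from all of its observations — a unit fixed effect. Only trends
are then matched, which matters when the treated unit's *levels* are
extreme outliers (Flint's are) but its trends resemble many districts.

**Joint weight fit.** One weight vector `w` on the unit simplex
(`w_i >= 0`, `sum w_i = 1`) is chosen to minimize the pooled squared
discrepancy between the treated unit's demeaned pretreatment trajectories
and the weighted control aggregate, summed over all selected outcomes:

```
min_w  sum_o  s_o^-2  sum_{t in pre(o)}  ( x̃_1t,o − Σ_i w_i x̃_it,o )²
```

where `x̃` are demeaned values and `s_o` is the outcome's pooled
pretreatment SD across the analytic sample (treated + donors), so
achievement scores and classification rates enter on a common scale. Each
outcome contributes only its available pre-years (math/reading 2007–14,
special needs 2006–14, attendance 2009–14) with no reweighting beyond the
per-year sum. Only lagged outcomes are balanced; no covariates, time
weights, or outcome modeling.

The program is a convex QP. It is solved by an active-set iteration on the
KKT system, warm-started from a penalty-augmented NNLS solution; the bound
multipliers are verified, so the returned point satisfies the KKT
conditions of the simplex-constrained problem (SLSQP is a fallback for a
stalled active set). A ridge term of 1e-8 on `||w||²` breaks ties among
non-unique minimizers (collinear donors) toward the smallest-norm weight
vector, making output deterministic. Weights below 1e-6 are reported as 0
and the rest renormalized, mirroring sparse published weight tables.

**Effects.** With pre/post period means `X̄_i`, `Ȳ_i` per unit,

```
ATT = (Ȳ_1 − X̄_1) − Σ_i w_i (Ȳ_i − X̄_i),
```

which is identically a weighted two-period difference-in-differences (the
tests assert equality to 1e-10 against an independent WLS regression
route). Yearly gaps are treated-minus-synthetic demeaned differences; the
ATT equals the mean of post-year gaps. Because the weights sum to one and
the estimate differences pre vs post, the ATT is exactly invariant to
common year shocks and to per-unit constant shifts. Per-outcome pre-RMSE
is reported in native units; the overall RMSE pools pre-period gaps after
dividing each outcome's gaps by its pooled *pretreatment* SD (whether the
published analysis standardized with pre-only or pooled moments is not
stated; pre-only is used here and recorded as a package choice).

## Donor-pool rules

Districts with fewer than 1000 students are removed first. Percentile
cutoffs on fraction Black and fraction economically disadvantaged are then
computed over the remaining districts *excluding the treated unit* (so the
treated district's extreme values cannot move its own comparison pool),
with nearest-rank inclusive percentiles — reproducible without
interpolation ambiguity. Presets: `U90` (union of top-decile sets, the
primary sample), `I75` (intersection of top quartiles), `U95` (union of
top 5% tails). Lowering the union percentile can only grow the pool;
raising the intersection percentile can only shrink it (property-tested).

## Inference

**Jackknife SEs.** For each donor `j`, weights and ATTs are refit from
scratch with `j` deleted (including recomputing the per-outcome scaling
SDs), and

```
SE² = (N_c − 1)/N_c · Σ_j (ATT_(j) − mean ATT_(·))²,   CI = ATT ± 1.96·SE.
```

Refitting rather than renormalizing captures uncertainty created by the
weight-selection process. The treated unit is never deleted. **Known
limitation:** this resampling scheme sees only donor-composition
uncertainty. The treated unit's own idiosyncratic noise — which
contributes a large share of the sampling variance of any post-minus-pre
contrast — is invisible to it, so under the default synthetic generator
the nominal 95% interval covers the truth in roughly 60% of replications
(the acceptance script reports the measured coverage). The published
analysis describes its SEs only as sandwich-type with jackknifed variance;
the delete-one-donor refit implemented here is one faithful reading of
that description, not a calibrated frequentist interval. No placebo or
permutation inference is provided.

**Subgroup equality tests.** Subgroup effects are compared with a stacked
two-way fixed-effects regression: control district-years carry their
synthetic-control weights, the two treated subgroup series enter
unweighted, and the design has unit effects, year effects, a post×treated
dummy, and a post×treated×(s=1) interaction. The interaction coefficient
equals `ATT^{s=1} − ATT^{s=0}` exactly (the year effects cancel in the
difference; asserted to 1e-8), with an HC3 heteroskedasticity-robust SE.
These regression SEs ignore weight-selection uncertainty, so subgroup
significance should not be read off outcomes whose overall effect was
itself insignificant.

## Subgroup decomposition

For a dichotomous student attribute `s` the per-category effects share the
*overall* fit's synthetic aggregate:

```
ATT^s = (Ȳ_1^s − X̄_1^s) − (Ȳ_syn − X̄_syn),
```

so the decomposition works even for attributes observed only inside the
treated district (home service-line material). Writing `p0, p1` for the
post-period average category shares and `Δp̄₁` for the post-minus-pre
change in the s=1 share,

```
ATT = p0·ATT^{s=0} + p1·ATT^{s=1} + Δp̄₁·(X̄_1^{s=1} − X̄_1^{s=0}).
```

Each `p` multiplies the ATT of its own category. The adjustment term's
sign follows from expanding `Ȳ_1 − X̄_1` with period shares: a category
whose share grew contributes its pretreatment mean positively. The
identity is exact (1e-10, property-tested over randomized panels) whenever
the overall treated series is the share-weighted average of the subgroup
series with shares constant within each period; with yearly share
variation inside a period the residual is bounded by the within-period
share wiggle times the subgroup spread. Relabeling which category is s=0
swaps terms and leaves the reconstruction unchanged; with `Δp̄₁ = 0` the
overall ATT lies between the two subgroup ATTs. Only dichotomous
decompositions are supported, and no per-subgroup synthetic control is
refit — both deliberate design restrictions.

Subgroup definitions: grade band is `<=5` vs `>=6`; a student is *mobile*
if they ever attend a district other than the treated one or leave the
state system without graduating; the socioeconomic index is the first
principal component of the correlation matrix of each student's multi-year
averages of economic-disadvantage, SNAP, and TANF indicators, oriented so
higher = more disadvantaged (positive loading on economic disadvantage)
and split at the median, ties going to the below-median (more
disadvantaged) side; service-line labels pool lead, galvanized steel, and
nonstandard materials as "lead" vs "copper", and exist only for
address-matched students. Standardization uses the population SD (divide
by n) of the reference distribution.

## Synthetic data generator

Because the motivating study's administrative data are restricted, the
package ships a generator that emulates the panel's statistical structure
and carries closed-form ground truth. District-year values follow an
interactive factor model

```
value(i,t,o) = a_io + λ_to + L_io·f_t + 1{i=1, t>=2015}·τ_o(t) + ε_ito
```

with the treated unit's loadings drawn as a convex combination of control
loadings (Dirichlet weights), so a zero-bias synthetic match exists; hull
membership can be switched off for stress tests. Defaults: 54 candidate
donors, years 2006–2019, treatment year 2015, two factors, and effects of
the magnitude the motivating study reports (math −0.15 SD, special needs
+0.012, reading and attendance near zero). Achievement levels are centered
at −0.30 SD with noise SDs (0.02 for scores, 0.003 for rates) chosen so
pretreatment RMSEs land in the low-hundredths range a well-fitting
district panel exhibits. The covariate table embeds the donor districts in
the demographic tail region the pool rules target, plus ~350 background
districts (including small ones) that realize the enrollment filter and
percentile cutoffs.

The student layer assigns each district ~120 students per year in
kindergarten-entry cohorts progressing one grade per year, with mobility
(2%/yr), out-of-state attrition (1%/yr), non-resident attendance (3%/yr),
gender/SES/service-line attributes (lead share 0.4, address-match rate
0.6), and additive subgroup level and effect offsets — constant within
subgroup, so every estimand is available in closed form. Treatment enters
through residence: a student living in the treated district in a post year
receives that year's effect, and a student exposed at the base year keeps
the effect after moving. Both the contemporaneous and the
invariant-assignment estimand therefore equal the configured ATT, giving
the selective-mobility stress test a well-defined truth: with
`selective_mobility > 0`, higher-ability exposed students preferentially
leave the treated district post-treatment, biasing the contemporaneous
estimate while base-year-frozen assignment recovers the truth. Share drift
is induced by category-dependent extra attrition. All randomness flows
from one seed through `numpy` seed-sequence spawning.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: serially correlated student outcomes
(special-needs status is redrawn each year rather than sticky), real
address-based record linkage, non-random test participation, grade
retention, district-size heterogeneity in the student layer, and any
attempt to match the real donor list or Flint's actual outcome levels.

## Numerical choices and problem sizes

Solver: KKT active-set with NNLS warm start, ridge 1e-8, reporting floor
1e-6 on weights; deterministic. Degenerate inputs raise typed errors
(zero-SD standardization cell, empty donor pool, treated unit missing
pre/post data, collinear TWFE design, subgroup shares not summing to 1).
The test suite scales Monte-Carlo checks to keep a full run under a
minute: 200-seed recovery studies use 20 donors at the panel level, and
student-layer checks use 8–10 donors with 40–130 students per district;
the acceptance script mirrors those sizes and finishes in about a minute.
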