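# Methods

This note documents the statistical model, the synthetic-data generator that
defines the package's test conditions, the numerical choices, and the known
limitations. Notation: :math:`{}_nq_x` is the probability of dying between
exact ages x and x+n under period rates; q without subscripts means
:math:`{}_{10}q_{15}` (youth mortality, ages 15–24); U5MR is
:math:`{}_5q_0`.

## Life-table conventions

Band probabilities compose and split through survival products:
`compose(q_a, q_b) = 1 − (1−q_a)(1−q_b)` for adjacent bands, with the exact
algebraic inverse for splitting. Central rates use the abridged relation
`m = q / (n − q(n − a))` with separation factor `a = n/2` for all bands
(uniform deaths within band). The youth segment of the survival curve is
near-linear, so the uniform-deaths assumption is accurate to well under a
percent at the mortality levels involved; no published separation factors
exist for this indicator, and the choice is exposed as an argument.
The annual rate of reduction is `100·ln(q_start/q_end)/years`. Printed
values round half away from zero, the convention that reproduces published
demographic tables; Python's default banker's rounding does not.

## The estimation model

Each country's log q trend is a cubic B-spline on knots spaced 2.5 years,
extended past the last observation so projection years are in-span.
Second-order differences of the coefficients are shrunk toward zero — i.e.
the trend is shrunk toward a straight line in log q — with a country scale
λ_c; log λ_c is pooled across countries (hierarchical normal), which is how
countries with little data borrow the typical degree of non-linearity from
data-rich ones.

The data model treats an observed q as the true risk times an error
multiplier, additive on the log scale:

- sampling error: the observation's known `se_logq`;
- non-sampling error: a per-source-type scale ω estimated from the data,
  with complete vital registration pinned near zero (1e−3);
- retrospective bias: sibling and census series carry a survey-level
  intercept b0_s and recall slope b1_s (bias grows linearly in the lag
  between field date and reference period), exchangeable across series
  through hierarchical normal priors. Biases are identified by overlap:
  where a survey disagrees with registration or other surveys covering the
  same years, the discrepancy is attributed to the survey;
- residual completeness error: incomplete-VR series that have been adjusted
  by an estimated completeness factor carry a level-only offset with a fixed
  N(0, 0.04²) prior. A completeness estimation error shifts an entire
  adjusted series multiplicatively, which no per-observation variance can
  express; 4% is the typical accuracy of the growth-balance method on the
  synthetic worlds used here. Sample registration systems carry no bias
  term.

Hyperpriors are weakly informative on the log-mortality scale:
μ0, μ1 ~ N(0, 0.5²); τ0, τ1, σ_λ and the ω's half-normal(0.5);
μ_λ ~ N(−3, 1); the level and slope components of the spline (the penalty
null space) get N(country mean log q, 2²). All are exposed in `B3Config`.

### Sampling

Fitting is by a seeded Metropolis-within-Gibbs sampler, 4 chains of
500 warmup + 1000 kept draws by default. A country's spline coefficients and
all of its series error terms are drawn **jointly** from their conjugate
Gaussian conditional (a blocked update on the extended design [B | Z]):
series-level offsets are nearly collinear with the spline level, and
single-site updates mix far too slowly (split-R̂ up to 1.27 at budgets where
the blocked sampler reaches 1.01). Bias-model means are conjugate; scale
parameters (τ, ω, λ_c, σ_λ) move by adaptive random-walk proposals on the
log scale tuned to 0.44 acceptance during warmup only. Chains run
sequentially with seeds derived from the configured seed, so every fit is
exactly reproducible. Convergence is summarised by split-R̂ and bulk ESS of
log q at 1990/2000/2019 (arviz); fits with R̂ ≥ 1.1 are flagged, never
silently accepted.

Projection to the target year needs no separate mechanism: the basis spans
the projection period, coefficients beyond the data are informed only by the
penalty, and the posterior fan widens accordingly. Crisis years are handled
by excluding observations for those years from the fit and combining each
draw with the excess-death probability in survival space,
`q ← 1 − (1−q)(1−q_excess)`; this is an additive shift in log-survival, so
interval widths are essentially unchanged.

## Completeness (generalized growth balance)

In a closed population the entry rate into the open interval x+ minus its
growth rate equals its death rate; with a fraction c of deaths registered,
regressing (entry − growth) on the registered partial death rate across open
ages 15+…65+ gives 1/c as the slope. The line is fitted by orthogonal
(total least squares) regression — both axes carry error, the standard
choice for death-distribution methods. The intercept absorbs relative census
coverage change. Uncertainty in ĉ is a delete-one jackknife over the
open-age points; it propagates into the adjusted series as a log-scale se
inflation (delta method) and, more importantly, into the level-only error
term in the estimation model. Adjusted series divide rates by min(ĉ, 1);
series with ĉ < 0.5 are dropped from the likelihood; series with ĉ < 0.95
are labelled incomplete. Multiple intercensal estimates interpolate linearly
between period midpoints. The synthetic-extinct-generations variant is not
implemented; GGB alone decides inclusion and adjustment.

## Quality screen

A log-quadratic regression of log q on log U5MR (and its square) over a
reference table supplies the expected pattern; a survey series whose pooled
q (inverse-variance weighted on the log scale) falls below the lower bound
of the 95% prediction interval at the series' paired U5MR is excluded.
Pooling is at series level because whole surveys, not individual windows,
suffer omission; exclusion is one-sided by design — overstated mortality is
never excluded. Registration data are never screened. In this package the
reference table is synthetic, generated from the world's own under-5 link
(`logquad_reference_pairs`); the fitted screen object is serialisable so an
external reference can be swapped in.

## Age split

Ratio observations r = (observed :math:`{}_5q_{15}`)/(median model q),
clipped to (0.01, 0.99) with a flag, are logit-transformed and smoothed over
time by penalised weighted least squares on the same B-spline basis with a
second-difference penalty; the penalty weight is chosen by generalized
cross-validation on a log-spaced grid (10⁻²…10⁶). With two or fewer
observations the fit is a constant at the weighted mean. The smoothed ratio
is applied to **every** posterior draw — :math:`{}_5q_{15} = r(t)\,q` and
:math:`{}_5q_{20}` from the survival identity — so the composition
identity holds exactly per draw and split uncertainty derives entirely from
the q posterior. No separate ratio uncertainty is propagated, matching the
single set of published intervals.

## Sparse-country fallback

Countries failing the data-richness rule (fewer than 4 usable observations,
or under 10 years between first and last reference time) are predicted from
U5MR: a linear mixed model of log q on log U5MR with random intercepts and
slopes by region, fitted by REML (statsmodels MixedLM), trained on the
spline-model posterior medians of the data-rich countries at 5-year grid
points — not on raw observations, so training targets are already
bias-corrected. Predictions condition on the region's estimated effects
(residual variance only); unseen regions use fixed effects with the
random-effect variance added. Draws are emitted in the same posterior format
as the spline model with a `source="sparse"` flag, so downstream stages
cannot distinguish the two. Singular random-effects fits fall back to OLS
with a warning. Residuals are treated as independent across years;
autocorrelation is a known limitation.

## Aggregation

Deaths per draw are central rate × person-years (mid-year population × 1
year); population counts carry no uncertainty. Regions sum member-country
deaths per draw exactly, and the world sums the regions, so conservation is
exact in floating point at both levels per band. Regional band
probabilities come back from aggregated rates (Σdeaths/Σperson-years), and
the regional q composes the bands, so the identities hold at every level.
Headline ARRs are computed on posterior medians with the per-draw ARR
distribution supplying the interval; printed medians of the two bands and
the total are each marginal medians, so their composition agrees only up to
rounding plus quantile slack (the per-draw identity remains exact).

## Out-of-sample validation

The training set keeps observations *collected* before the cutoff
(default 2013) — the split is by field date, so a recent survey's whole
retrospective series is withheld together; with the default world roughly a
quarter of observations are withheld. Errors are observed minus predicted,
in deaths per 1000. Coverage is scored against the predictive interval for
a new observation: latent q draws at the observation's time, plus the
series error term (the series' own posterior draws when the series
continues from training, fresh draws from the bias hierarchy for new
series), plus sampling and source noise. Using the latent interval alone
would be wrong — a test asserts the two differ. "Nominal" coverage for the
90% interval is operationalised as the band [0.85, 0.95].

## The synthetic world

`generate_truth` draws each country's log q path as regional intercept +
country intercept + linear slope + an integrated random walk (zero initial
level and velocity, innovation SD 0.002/yr) — the same locally-linear
process family the model's penalty encodes, making the world well-specified
for the estimator. Defaults place median 2019 youth mortality near
12 per 1000, declining ~1.5%/yr, consistent with published global levels.
log U5MR follows a log-linear link from log q plus country noise (SD 0.15),
so the screen's reference relation exists in-world. The ratio
:math:`{}_5q_{15}/{}_{10}q_{15}` is a slowly drifting logit path bounded in
(0.2, 0.8).

Observation generators are pure functions of (parameters, seed): VR draws
true deaths binomially from the hazard and thins them by completeness;
sibling surveys produce one observation per 5-year recall window over a
15-year horizon, with survey-level b0 ~ N(0, 0.1²) and recall slope
b1 ~ N(−0.01, 0.01²) per year of lag, sampling error from an effective
exposure of 150 000 person-years per window with design effect 1.5, and
non-sampling noise (SD 0.05); censuses thin 12-month household deaths by a
reporting factor (default 0.95). The default world mixes complete-VR,
incomplete-VR + survey, survey/census-only, and sparse countries
(35/25/30/10%), with a quinquennial survey programme. Stable-population
inputs for the completeness method use a Gompertz-plus-child-hump schedule,
constant growth, and 1% lognormal noise on all reported counts.

What the generator does **not** emulate: individual-level sibling microdata
(age heaping, selective omission patterns), migration, HIV-type mortality
humps, and correlated non-sampling errors across surveys of the same
programme. Passing tests therefore demonstrate correct recovery under the
stated error structures, not robustness to every defect of real data.

## Problem sizes and numerical choices

The validation suite runs reduced problems chosen for precision per unit
time: the recovery test uses the default 20-country world at 4 chains ×
1000 draws; predictive-coverage checks pool three 40-country worlds
(~700 scored observations), because per-world coverage with few countries
is dominated by country-level clustering of latent-fan errors. Replicate
counts (100 per completeness level, 500–1000 screen surveys) put
Monte-Carlo error well inside the asserted tolerances. GCV grids, ridge
guards (1e−8 on the penalty null space), clipping bounds and adaptation
constants are stated in the code next to their use.

## Known limitations

- Both-sexes-combined only; no sex-specific estimation.
- The error multiplier model identifies biases only where sources overlap;
  survey-only countries' levels rest on the hierarchical bias priors.
- The completeness level-error scale (0.04) is fixed, not estimated.
- ARR intervals are draw-wise; medians-based point estimates can differ
  slightly from the median of draw-wise ARRs.
- Posterior predictive checks beyond the out-of-sample design (e.g. PIT
  histograms) are not implemented.
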