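# Methods

`microdem` simulates a female population of a country undergoing rapid
demographic and socioeconomic transition, stratified by single-year age,
urban/rural residence, educational attainment (0, 1–5, 6–12, >12 years of
schooling) and migration history, and calibrates nested variants of the
model to survey-style targets by MCMC with DIC-based selection.

## Population state and life tables

Counts live on a dense grid `(age 0..110) × (urban, rural) × (4 education
categories) × (migration history)`. Migration history is kept as
years-since-last-move (never, 0, 1, …, 11, 12+), which answers the survey
lookback questions "moved within the last 6 years / 12 years / ever"
exactly; because a move always toggles residence, the direction of the
last move is implied by current residence and is reported, not stored.

The terminal age 110 is closed with the exponential residual
`L(110) = l(110)/h(110)`; within ages, survivorship decays as
`l(x+1) = l(x)·exp(−h(x))` and person-years use the trapezoid
`L(x) = (l(x)+l(x+1))/2`. Period life expectancy is the sum of
person-years per birth. The trapezoid overestimates person-years when a
single-year hazard is extreme (an infinitely lethal first year yields
e₀ → 0.5, not 0); this is irrelevant at demographic hazard levels.

## Fertility

Cumulative births per woman up to age *t* follow the double-exponential
curve

    G(t) = F · (1/2)^(r^((t−a)/b)),   r = ln 0.95 / ln 0.05,

with quantum *F* (lifetime births per woman), median age of childbearing
*a* (G(a)=F/2) and rise interval *b* (ages spanning 5%→95% of F differ by
exactly *b*). Annual age-specific rates are first differences of G and
telescope to F. A linear secular trend acts on the quantum only
(`F_eff(y) = max(0, F + trend·(y − y₀))`): trending *F* changes how many
children are born, not when, which is the most parsimonious reading of a
single "linear trend in fertility"; *a* and *b* are time-invariant per
stratum. Newborn girls are `fraction_female` (default 0.487, the human
sex ratio at birth) of all births, enter at age 0 with their mother's
current residence, and draw an education category from the birth-cohort
distribution below.

## Mortality

An aggregate mortality rate is a mixture of education-specific rates:
with `p` the education composition and `RR` relative risks against the
reference group (rural, no schooling; RR ≡ 1),

    μ_agg = μ_ref · Σₑ pₑ·RRₑ     and inversely     μ_ref = μ_agg / Σₑ pₑ·RRₑ.

The reference rate follows a Lee–Carter-type log-linear surface per
residence and age cluster (<1, 1–10, >10 years):

    log μ_ref(age, year) = c + β_year·(year − y₀) + β_age·(age − a₀),

centered at the simulation start year and the cluster mid-age so the
intercept and slopes decorrelate during calibration (a pure
reparameterization). Relative risks are age-invariant within residence
and apply at all ages; education is assigned at birth, so this is
internally consistent. The simplest model variant sets RR ≡ 1 and fits
the surface to aggregate rates directly.

## Annual transitions

Each simulated year, death and migration compete:
`P(event i) = (hᵢ/H)(1 − e^{−H})`, `P(none) = e^{−H}` with `H = Σ hᵢ`.
Survivors age one year (age 110 is absorbing), move counters advance,
movers switch residence with a reset counter. Births are computed from
start-of-year exposures — women who die within the year still contribute
that year's births, a deliberate intra-year ordering choice (the true
ordering within a year is unknowable at annual resolution; this one
preserves the exact bookkeeping identity N(t+1) = N(t) − deaths +
births, with migration internal). Migration hazards are linear in
calendar year per direction and education, clamped to [0,1]; the
urban→rural direction exists in the parameterization but is pinned to 0
in calibration (a net-rate reading).

Education categories of newborn cohorts drift linearly per residence and
are projected onto the simplex by truncation-at-zero and
renormalization. Because attainment is fixed at birth, the prevalence
among 20–24-year-olds in later years reproduces the birth-cohort trend
by construction.

Two execution modes share the state: expected-value (deterministic
fractional flows — smooth, used inside calibration) and stochastic
(multinomial draws per stratum and Poisson births, integer counts). The
stochastic mode derives one generator per (seed, calendar year), so
scenario arms run with common random numbers: arms whose parameters
coincide produce bitwise-identical trajectories.

## Targets and likelihood

Five calibration target classes (children ever born by maternal age
band, probability of death by year/age band/residence, education
prevalence at ages 20–24, migration lookback proportions, population
size by year/residence) plus held-out life-expectancy rows for external
validation. Each row is an independent Normal with
`σ = (ci_high − ci_low)/3.92`, floored at max(1% of the estimate,
1e−9) so degenerate intervals cannot dominate; the deviance is −2·log L.
Proportions are fit on the natural scale. All model variants are scored
on the full calibration set — variants lacking migration predict zero
lookback proportions, the simplest variant predicts a frozen education
mix — because DIC comparison requires a common likelihood.

Children ever born for an age band is evaluated as G at the band's
mid-age with the survey-year quantum (a period approximation of a cohort
quantity, consistent on both the generator and the model side).

## Calibration

Priors are vague uniforms on bounded ranges (quantum 0.05–10 births,
median age 12–40 y, rise interval 1–30 y, log-rate intercepts −12…−0.5,
year slopes ±0.15/y, age slopes ±0.6/y, RR 0.05–2, migration base rate
0–0.2/y). The sampler is a random-scan block Metropolis over natural
parameter groups (one fertility curve, one mortality cluster, the RR
vector, per-education migration pair, per-residence education trends)
with per-block scale adaptation toward 20–40% acceptance and
Haario-style empirical-covariance proposals learned during burn-in.

Finding the 71-parameter posterior's typical set from uniform prior
draws is hopeless at desk scale, so the default initialization locates
the mode once: method-of-moments estimates read directly off the targets
(the quantum from the oldest children-ever-born band, log-rate
regressions for the mortality surface, prevalence slopes for education
trends, lookback/6 for migration), a few block-coordinate Nelder–Mead
sweeps, then Gauss–Newton refinement of the weighted least-squares
objective. The Jacobian at the solution gives a Laplace covariance that
seeds the proposal covariances and the overdispersed chain starts
(mode ± 1 posterior sd, seeded per chain). `init="prior"` restores fully
dispersed uniform starts for whoever has the iteration budget.

Convergence is monitored with the potential-scale-reduction statistic
(R-hat < 1.1 across ≥2 chains). Model selection uses
`DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)` with θ̄ the pooled posterior mean
re-evaluated through the simulator (projected into bounds with a logged
warning if needed); differences >10 are flagged meaningful, ties select
the simplest variant.

## Synthetic world

The generator states one world and leaves it alone: 10⁵ women at start
(targets are scale-free except population sizes, generated on the
synthetic scale), 26% urban, a smooth quasi-stable pyramid, education
assigned per birth cohort so attainment already trends across living
cohorts. Fertility quantum 4.5→2.2 (rural E0→E3) and 3.6→1.8 (urban)
declining ~0.03/y; mortality surface chosen to give a period e₀ of
≈63–65 years at the 1992 start rising ≈6 years by 2010 (year slopes
−0.02…−0.03); relative risks of death decline monotonically with
education (urban 0.92/0.76/0.55/0.38, rural 1/0.89/0.72/0.56);
rural-to-urban migration 0.003–0.012/y rising with education and
drifting upward; education trends shift mass from no-schooling toward
higher categories. Three survey waves at years 1, 7 and 14 of the
horizon mirror the spacing of the 1992-3/1998-9/2005-6 national family
health survey rounds; mortality, population and life-expectancy series
are annual over the first 17 years.

Noise: 95% CI half-widths of 5% (rates/proportions) and 2% (population
sizes), with draws of sd = half-width/1.96 so the written intervals are
calibrated. Noisy education prevalences are renormalized per survey
group and lookback windows re-sorted to preserve their nesting —
otherwise the generator's output would violate its own validation rules.
What a green calibration test establishes: parameter recovery under
correctly specified, independent Gaussian noise. What it does not:
robustness to survey design effects, correlated errors, model
misspecification, or real-world measurement bias.

## Scenarios

The static comparator zeroes every secular trend (fertility trend,
mortality year-slopes, migration trends, education trends), leaving
start-year levels untouched — the conventional fixed-exposure model.
The education intervention moves the no-schooling probability mass of
rural birth cohorts born in or after the intervention year into the
1–5-years category (education is fixed at birth, so living cohorts are
untouched; retroactive re-education is deliberately not modeled). All
effects of the intervention flow through the education-conditional
rates (mortality RR, fertility, migration), nothing else is touched.
The difference-in-differences report is, per posterior draw and year,
(ΔLE under the trend-aware model) − (ΔLE under the static model), with
the median and central 95% band across draws.

## Numerical notes and limitations

- Expected-value flows make the likelihood smooth but treat strata as
  continuous masses; stochastic runs are for final uncertainty only.
- The far tails of the fertility curve underflow to exactly 0/F in
  float64; all identities hold to ≥1e−9 where mass is non-negligible.
- Weakly identified parameters (e.g. relative risks confounded with the
  urban intercepts when education composition moves slowly) keep wide
  posteriors; the Laplace-capped start dispersion prevents them from
  throwing chains into regions where extrapolated education
  distributions lose all mass (those evaluate to −inf and are
  rejected).
- Desk-scale MCMC settings (thousands, not hundreds of thousands, of
  iterations) are calibrated for CI budgets; R-hat is reported and
  warnings are logged when chains disagree.
- Males, household structure, parity-specific fertility, cause-specific
  mortality, international migration and intra-urban/rural moves are
  out of scope.
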