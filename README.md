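# microdem

Demographic microsimulation of a female population undergoing rapid
demographic and socioeconomic transition — with Bayesian calibration to
survey-style targets and information-criterion selection among nested
model structures.

Health-policy simulation models routinely hold demographic and
socioeconomic exposures fixed at their baseline values. In countries
urbanizing and educating quickly, that assumption distorts projected
population sizes, life expectancy, and estimated intervention benefits.
`microdem` is a compact laboratory for quantifying that distortion: it
simulates annual birth cohorts of women stratified by age, urban/rural
residence, educational attainment (0, 1–5, 6–12, >12 years of
schooling) and migration history, with secular trends in fertility,
mortality, education and rural-to-urban migration; calibrates three
nested model variants to survey-style data by MCMC; selects among them
with the deviance information criterion (DIC); and contrasts the chosen
model with its "static" equivalent (all trends frozen), including a
universal-primary-education intervention analysis.

## The model in brief

* **Fertility** — cumulative births per woman up to age *t* follow
  `G(t) = F · (1/2)^(r^((t−a)/b))` with `r = ln 0.95 / ln 0.05`:
  *F* is the lifetime quantum, *a* the median age of childbearing
  (`G(a) = F/2`), *b* the 5%→95% rise interval. Annual age-specific
  rates are first differences of *G*; a linear secular trend acts on
  *F*.
* **Mortality** — aggregate rates decompose by education via relative
  risks against the rural/no-schooling reference,
  `μ_agg = μ_ref · Σₑ pₑ RRₑ`; the reference rate follows a
  Lee–Carter-type surface
  `log μ = c + β_year(year − y₀) + β_age(age − a₀)` per residence and
  age cluster (<1, 1–10, >10 years).
* **Transitions** — death and migration compete within each year
  (`P(event i) = (hᵢ/H)(1 − e^{−H})`); education is assigned at birth
  from a linearly trending residence-specific distribution; migration
  history is tracked so survey lookback questions (moved within 6 / 12
  years / ever) are answered exactly.
* **Calibration** — independent Gaussian likelihood per target row with
  `σ = CI width / 3.92`; adaptive block Metropolis seeded by
  method-of-moments + Gauss–Newton mode finding; R-hat convergence
  checks; `DIC = D̄ + p_D` with Spiegelhalter's `p_D = D̄ − D(θ̄)`.

A built-in synthetic-world generator (`microdem.make_truth`) emulates
the statistical structure of the five real data classes (three survey
waves of children-ever-born, education prevalence and migration
lookback; annual death probabilities and population sizes; held-out
life expectancy), so the whole pipeline is testable end-to-end with no
external data. See `docs/methods.md` for the full model account.

## Worked example

```python
import microdem as md

# a known ground truth: declining fertility and mortality, education
# gradients in death risk and migration, 100k women from 1992
scenario = md.make_truth("full_effects", seed=1)
targets, initial = md.generate_targets(scenario)   # noisy survey-style targets

# calibrate the full model variant and check parameter recovery
problem = md.CalibrationProblem("v3", targets, initial)
chains = md.mcmc_run(problem, md.McmcSettings(iterations=8000, burn_in=3000,
                                              n_chains=4, seed=3))
report = md.recovery_report(chains, scenario)
print(report.attrs["coverage"])          # fraction of parameters whose 95% CrI covers truth
print(report[report.parameter == "fert_F_rural_E0"].iloc[0].to_dict())
```

Output from this exact run:

```
0.789
{'parameter': 'fert_F_rural_E0', 'truth': 4.5, 'posterior_median': 4.561,
 'ci_low': 4.489, 'ci_high': 4.633, 'covered': True, ...}
```

The rural no-schooling lifetime fertility (truth 4.5 births/woman) is
recovered with a credible interval of about ±0.07; all eight
stratum-level quanta are covered. Overall coverage is below 95% because
weakly identified parameters (e.g. relative risks confounded with
residence intercepts) mix slowly at desk-scale chain lengths.

The scenario contrast runs the four arms (dynamic/static ×
baseline/intervention) under common random numbers:

```python
cfg = md.SimulationConfig(start_year=1992, end_year=2025, seed=1)
arms = md.run_four_arms(scenario.params, scenario.initial_state, cfg,
                        intervention_year=2000)
did = md.diff_in_diff_life_expectancy(
    (arms["dynamic_base"].life_expectancy, arms["dynamic_intervention"].life_expectancy),
    (arms["static_base"].life_expectancy, arms["static_intervention"].life_expectancy))
```

Under the declining-trend truth the static comparator overshoots the
horizon-end population and undershoots life expectancy, and the two
models disagree about the intervention's life-expectancy benefit — the
difference-in-differences series `did` quantifies by how much.

## Command line

```bash
microdem synth --scenario full_effects --seed 3 --out data/
microdem simulate --params data/truth.json --initial data/initial_population.csv \
                  --start 1992 --end 2025 --out traj.csv
microdem calibrate --variant v3 --targets data/manifest.yaml \
                   --initial data/initial_population.csv --out fits/
microdem select --chains fits/ --out dic_table.csv
microdem compare-static --params data/truth.json --initial data/initial_population.csv \
                        --start 1992 --end 2025 --out report/
microdem pipeline --scenario full_effects --seed 3 --out run/
```

Every command writes a config + seed snapshot to its output directory
before computing, so artifacts are reproducible from their logs.

## Acceptance script

`scripts/acceptance.py` exercises the full pipeline from scratch:
synthetic world → targets → MCMC calibration of all three variants →
DIC selection → parameter-recovery report → four-arm scenario analysis
with the difference-in-differences summary.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints a run summary (selected variant, DIC table, recovery
coverage, horizon-end difference-in-differences) and writes the results
file.
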