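# harvestssm

Bayesian state-space estimation of harvested wildlife abundance from
age-at-harvest registries.

The package implements a two-stage state-space model for a hunted,
two-sex, ten-age-class population observed only through its harvest:

* **process model** — stage-structured projection with harvest-season and
  non-harvest-season survival, age-specific fecundity with a two-year
  recruitment lag, an absorbing terminal age class, and cub
  back-calculation;
* **observation model** — a two-part harvest likelihood: Poisson for the
  total registered harvest, multinomial over age/sex classes for the
  aged-and-sexed subset;
* **priors** — a packaged, literature-informed prior set (gamma litter
  sizes, beta pregnancy rates and sex proportion, hierarchical
  complementary-log-log survival priors with annual precision
  hyperpriors), loadable/serializable as YAML;
* **inference** — adaptive blocked random-walk Metropolis with a Laplace
  preconditioner, Gelman–Rubin diagnostics, and posterior summaries for
  every demographic parameter and annual total abundance;
* **sensitivity** — the ±10% prior-bias scenario grid over nine
  parameters (plus post-hoc ±50% initial-population tests) with percent
  relative change (PRC) and coefficient of variation (CV) statistics;
* **synthetic data** — a registry generator with a known-truth ledger so
  the full pipeline is testable without the original (non-redistributable)
  registry;
* **evaluation** — CPUE computation, trend regression, and credible-interval
  coverage checks against external estimates.

## Command-line usage

```bash
# generate a synthetic 8-year registry shaped like the study data
harvestssm simulate --fixture paper_shape --seed 1 --out sim_out

# validate any registry CSV against the data invariants
harvestssm validate sim_out/paper_shape_registry.csv

# fit the state-space model (desk-scale chains by default; --full for
# the production 220k x 3 configuration)
harvestssm fit sim_out/paper_shape_registry.csv --out fit_out --seed 0

# prior-bias sensitivity grid (16 feasible scenarios + reference fit)
harvestssm sensitivity sim_out/paper_shape_registry.csv --out sens_out --posthoc

# evaluation report: CPUE trend regression and CrI coverage
harvestssm report fit_out --cpue permits.csv \
    --registry sim_out/paper_shape_registry.csv --external 2011 23000
```

The registry dialect is a long CSV with columns `year`, `sex` (`F`/`M`/`U`),
`age_class` (`1.5` … `9.5`, `10.5+`, `unknown`), `count`; yearly totals
are the sums including unknown rows.

## Library entry points

```python
import harvestssm as h

priors = h.build_default_priors()
data, truth = h.simulate(h.SimulationDesign(seed=1))
fit = h.run_mcmc(data, priors, h.desk_config(seed=0))
fit.summary()                 # posterior means, sds, 95% CrIs
fit.rhat()                    # Gelman-Rubin per parameter
results, ref = h.run_sensitivity(data, priors, h.desk_config(seed=0))
```
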