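# beechsurv

Bayesian growth–survival analysis of tagged-tree remeasurement data along an
elevation gradient, built around the kind of permanent-plot study run in
monodominant mountain beech (*Nothofagus solandri* var. *cliffortioides*)
forest in New Zealand's Southern Alps: 216 plots of 0.04 ha on 85 transects
between 640 and 1417 m elevation, every stem ≥ 30 mm diameter tagged and
remeasured eight times between 1974 and 2009, with a magnitude-6.7
earthquake striking the forest between the 1993 and 1999 measurements.

The package is for forest demographers who have (or can request) this style
of tagged-tree table and want to ask: *how does a tree's recent diameter
growth predict its survival, and how does that relationship change with
elevation and with disturbance?* Because the archival field data are
request-only, the package ships a synthetic-forest generator that reproduces
the study's statistical structure exactly, so the entire pipeline is
testable end to end.

## The model

A tree alive at measurement *t−1* survives to *t* with probability
*S*<sub>i,t−1</sub><sup>Δt</sup>, where *S* is its **annual** survival
probability and Δt the interval length in years. *S* is modelled on the
logit scale with coefficients that take separate values in each of three
survival periods *eq* (pre-earthquake 1983–1993; 0–5 years post-earthquake
1993–1999; 5+ years post-earthquake 1999–2009):

```
logit S_{i,t-1} = μ_S,eq + γ_y,eq y_{i,t-1} + γ_y²,eq y²_{i,t-1}
                + γ_bas,eq bas_{i,t-1} + γ_bas×ele,eq bas_{i,t-1} ele_j
                + γ_G,eq G_{i,t-2} + γ_G×ele,eq G_{i,t-2} ele_j
                + γ_G1,eq G_{i,t-3} (+ γ_G1×ele,eq G_{i,t-3} ele_j)
                + γ_dist,eq dist_j + γ_avP,eq avP_j + γ_LI,eq LI_j
                + γ_ele,eq ele_j + ε_j ,      ε_j ~ N(0, σ_S²)
```

with *y* tree diameter (centred at 164 mm), *bas* local basal area of all
neighbours in a 15 m × 15 m window around the tree's 5 m × 5 m subplot
(centred at 50 m² ha⁻¹), *G* and *G1* previous and lagged annual growth
(mm yr⁻¹, the two measurement windows preceding the survival interval),
and plot covariates soil-available P (ln, centred at ln 14.88), landform
index (centred 20°), elevation ((m − 1000)/100) and ln distance from the
earthquake epicentre (centred at ln 18.17). Outcomes are Bernoulli in the
interval survival probability; posterior sampling is an adaptive
Metropolis-within-Gibbs scheme; candidate models (all admissible
combinations of the growth covariates and their elevation interactions on
top of the base covariates — nine in total) are compared by WAIC.

## Worked example

```python
import beechsurv as bs

# a small synthetic forest with known truth
cfg = bs.SimulationConfig(seed=7, n_plots=20, n_transects=8,
                          stems_per_subplot=2.5)
dataset = bs.simulate_forest(cfg)
obs, exclusions = bs.assemble_observations(dataset.trees, dataset.plots)
print(len(obs), "tree x interval observations,",
      (obs.outcome == 0).sum(), "deaths")

est = bs.BayesianTreeSurvival(seed=11, chains=3, iterations=900,
                              burn_in=300, thin=3).fit(obs)
print(est.draws_["mu[1]"].mean().round(2),
      "posterior mean pre-earthquake logit survival",
      "(truth 3.69)")
print(float(bs.annual_survival(est.draws_["mu[1]"].mean())).__round__(3),
      "annual survival at covariate zero")
```

prints (exactly, with these seeds):

```
824 tree x interval observations, 59 deaths
5.03 posterior mean pre-earthquake logit survival (truth 3.69)
0.993 annual survival at covariate zero
```

Annual survival at "covariate zero" is high — mountain beech is long-lived
and mortality signal accrues slowly. With only 20 plots and 59 deaths the
intercept posterior is wide (here its mean overshoots the generating value
by more than one logit while the 95% interval still covers it); at the full
216-plot design the intervals tighten enough to separate the
period-specific growth effects, which is what the recovery study in
`scripts/acceptance.py` measures.

The same workflow is available from the shell:

```bash
beechsurv simulate --seed 1 --out data/
beechsurv prepare --trees data/trees.csv --plots data/plots.csv --out data/observations.csv
beechsurv fit --observations data/observations.csv --model selected --seed 1 --out data/fit.nc
beechsurv select --observations data/observations.csv --seed 1 --out data/ranking.csv
beechsurv report --fit data/fit.nc --observations data/observations.csv --out data/
beechsurv run --config config.yaml --out results/   # everything at once
```

## Layout

| module | contents |
| --- | --- |
| `beechsurv.data_model` | domain types, validation, CSV readers/writers (schema in `schemas/tables.yaml`) |
| `beechsurv.synthetic` | the synthetic forest generator and measurement-error overlay |
| `beechsurv.prepare` | growth windows, outlier imputation, local basal area, standardization, observation assembly |
| `beechsurv.model` | the survival model, `BayesianTreeSurvival` estimator, curves |
| `beechsurv.selection` | the nine candidate models, deviance, WAIC, ranking |
| `beechsurv.report` | posterior summary tables, basal-area series, pipeline orchestration |
| `beechsurv.validation` | simulation-based validation studies used by the tests and the reproduction script |
| `beechsurv.cli` | the `beechsurv` command-line interface |

See `docs/methods.md` for the statistical details, default choices and
known limitations.
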