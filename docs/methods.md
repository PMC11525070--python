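# Methods

## The survival model

Survival is observed as interval-censored binary data: a tagged tree alive
at one measurement is either alive or dead at the next, Δt = 4–6 years
later. The model treats annual survival *S* as constant within an interval,
so the interval survival probability is *S*^Δt — no finer hazard shape is
attempted, because nothing in a two-point observation can identify one.
The pointwise log-likelihood of an observation with outcome *a* ∈ {0,1} is

    a · Δt · ln S + (1 − a) · ln(1 − S^Δt),

which reduces to the ordinary Bernoulli log-likelihood at Δt = 1. The unit
of observation (and of the WAIC pointwise decomposition) is the tree ×
survival interval.

Logit *S* is linear in tree-level covariates (diameter, diameter², local
basal area, basal area × elevation, previous growth, previous growth ×
elevation, lagged growth, optionally lagged growth × elevation) and
plot-level covariates (soil-available P, landform index, elevation,
distance from the earthquake epicentre), plus one Gaussian plot random
effect ε_j shared by all of a plot's trees **across all periods** (the
sharing is an assumption; nothing in the data structure forces it, but
plot quality is persistent and a per-period plot effect would be poorly
identified with only one or two intervals per period). Every fixed
coefficient takes a separate value in each of the three survival periods —
pre-earthquake, 0–5 years post-earthquake, 5+ years post-earthquake — so a
single fit yields period-specific growth–survival relationships.

Growth covariates are aligned as in the field protocol: for the survival
interval starting at schedule year *t*, previous growth is the annual
diameter increment over the measurement window ending at *t* and lagged
growth the window before that (for 1983–1987: 1978–1983 and 1974–1978).
A tree therefore needs two complete prior windows before it contributes an
observation; recruits enter the model two windows after tagging. Negative
computed growths are retained — they are mostly measurement noise on a
slow-growing species, and dropping them would bias growth upward.

## Covariate standardization

Covariates are centred at fixed, design-level constants rather than sample
means, so coefficients are comparable across datasets: basal area at
50 m² ha⁻¹, diameter at 164 mm, ln soil-P at 2.7 (= ln 14.88 µg g⁻¹),
landform index at 20°, ln epicentre distance at 2.9 (= ln 18.17 km),
elevation at 1000 m. Elevation is additionally divided by 100 m: with raw
metres, a coefficient of ~0.24 per unit across a 640–1417 m range would
imply absurd logit swings, so the natural reading of the printed effect
sizes is per 100 m. The divisor is configurable and recorded. Growth
covariates enter in raw mm yr⁻¹ (their natural zero is meaningful).
Diameter² is the square of the *centred* diameter.

## Data preparation

* **Local basal area** (the neighbourhood-competition index) sums stem
  cross-sections of all living trees whose 5 m × 5 m subplot falls in the
  3 × 3 block (15 m × 15 m, 0.0225 ha) centred on the focal tree's subplot.
  Positions are recorded only to subplot, so the window is discretized to
  subplots. Survival observations are restricted to the four central
  subplots, whose windows never cross the plot boundary; all plot trees,
  any subplot, contribute to their neighbours' basal area. Dead trees
  contribute zero from the first measurement at which they are recorded
  dead.
* **Outlier rule**: any window growth rate strictly above 10 mm yr⁻¹ or
  strictly below −3 mm yr⁻¹ flags the tree (boundary values are kept).
* **Imputation**: a flagged or missing diameter is replaced by the nearest
  reliable measurement of the same tree plus the median growth of
  same-plot trees in the same diameter tercile over the same window(s),
  walking window by window across gaps. The rule is deterministic, the
  imputed year is recorded on the tree, and trees with no usable anchor are
  excluded with a logged reason — every exclusion is auditable.
* Death is absorbing; a tree alive at an interval start but unrecorded at
  the end is excluded from that interval (not treated as dead).

## Priors and MCMC

The priors are weakly informative defaults (none are stated by the field
protocol): independent Normal(0, 10²) on all fixed effects on the logit
scale, half-Normal(2) on σ_S. At the data sizes involved (hundreds of
deaths) they are numerically irrelevant except for guarding against
separation; halving or doubling the scales moves posterior means by far
less than one posterior sd.

The sampler is adaptive Metropolis-within-Gibbs, chosen for exactness and
zero external dependencies:

* Within each period the design block is **centred** (non-intercept
  columns have their period mean subtracted) before sampling; the centred
  intercept is mapped back to the reporting scale when draws are recorded,
  and priors are evaluated on the reporting-scale coefficients. This
  removes the severe intercept–covariate posterior correlations that
  otherwise cripple coordinate-wise updates.
* Each coefficient gets a scalar random-walk update with a proposal scale
  adapted toward 44% acceptance; each period additionally gets a
  full-block multivariate-normal update whose covariance is learned during
  burn-in (Haario-style) — this handles the remaining correlations
  (diameter with diameter², previous with lagged growth).
* Plot effects are conditionally independent given the coefficients, so
  all 216 are proposed and accepted/rejected in one vectorized step; σ_S
  uses a log-scale random walk with the Jacobian correction; an extra
  likelihood-invariant move shifts all period intercepts against the plot
  effects to decorrelate the two.
* All adaptation (scalar scales, block covariances, the recentring scale)
  is **frozen at the end of burn-in**, so the retained chain is a valid
  fixed-kernel Metropolis sampler.

Protocol: the desk-scale default is 3 chains × 6,000 post-burn-in
iterations with 1,000 burn-in, thinned by 3 (6,000 retained draws); the
archival-scale protocol (150,000 / 10,000 / 3) is available by
configuration. `iterations` counts post-burn-in iterations, so retained
draws = chains × iterations / thin. Convergence is reported as split-R̂
and effective sample size per fixed effect; R̂ > 1.05 attaches a warning
to the fit, never a silent pass. Fixed seed ⇒ bit-identical draws. At the
full 216-plot design the desk protocol reaches max split-R̂ ≈ 1.01 in
about three minutes on one CPU.

Pointwise log-likelihood matrices are stored float32 (6,000 draws ×
~18,000 observations ≈ 420 MB); the precision loss is orders of magnitude
below the ΔWAIC ≈ 1 decision scale.

## Model comparison

WAIC = −2(lppd − p_waic), with lppd computed by log-sum-exp over draws and
the variance-form penalty p_waic = Σᵢ Var(log-lik_i) using the sample
(n−1) variance; the reference arviz implementation (population variance)
agrees to well under one WAIC unit at realistic draw counts and serves as
an independent cross-check in the tests. The nine candidates are every
admissible combination of {previous growth, lagged growth} × {main only,
main + elevation interaction} on top of the base covariates; interactions
are never included without their main effect. Candidates are fitted
independently (no warm starts) for reproducibility; exact WAIC ties rank
the more parsimonious model first. The per-draw deviance −2 Σᵢ log-lik_i
is summarized alongside.

The inference default is the model with both growth main effects and the
previous-growth × elevation interaction only; the full model (both
interactions) is one flag away. Printed WAIC magnitudes from the original
field data are not comparable to synthetic-data values (they depend on the
exact pointwise unit and penalty variant and on the real data); only
directions and differences are meaningful targets.

## The synthetic forest

The generator's purpose is to make every downstream stage testable with
known truth, not to be a forest simulator in its own right.

What it emulates: 216 plots of 20 m × 20 m on 85 transects of 1–8 plots;
elevations spanning 640–1417 m; plot covariates centred near the
standardization zero-points; ~5.5 initial stems ≥ 30 mm per 5 m × 5 m
subplot (≈ 4,500 trees in the four central subplots of all plots, local
basal area distributed around 50 m² ha⁻¹); eight measurements 1974–2009;
log-linear diameter growth declining with elevation and local basal area
and rising weakly with size, with persistent tree-level variation
(log-scale sd 0.45) and per-window noise (sd 0.5), capped at a
physiological 8 mm yr⁻¹ — this reproduces a realistic growth distribution
(median ≈ 0.9 mm yr⁻¹, roughly half of trees at or below 1 mm yr⁻¹, a
fast tail past 4 mm yr⁻¹); recruitment at 30 mm at a configurable rate;
survival outcomes drawn from **exactly** the likelihood the model fits,
with true coefficients defaulting to the published posterior means for
this forest (strong previous-growth effects, positive pre-earthquake
elevation effect, large positive period-2 distance effect, σ_S = 0.966).

The earthquake enters the truth through the period-2/period-3 coefficient
values. The optional overlay adds (a) distance-dependent injury whose only
consequence is persistent growth suppression after 1993 — this feeds
survival through the model's own growth covariates and so keeps the
likelihood exact — and (b) distance-dependent excess mortality in
1993–1999, which **defaults to zero** because any unmodelled extra
mortality would break the exact-likelihood property the recovery checks
rely on.

Two deliberate exogeneity choices, made because the package's recovery
checks would otherwise test the wrong thing:

1. The plot random effect is applied only to the central-subplot trees
   (the modelled subpopulation). If the same effect drove neighbour
   mortality for 35 simulated years, local basal area would accumulate the
   effect's mortality history and become an endogenous covariate —
   empirically this biased the basal-area coefficients by ~3 posterior sd
   in every period, with no error anywhere in the fitting machinery.
2. The 216 plot effects are drawn iid N(0, σ_S²) and then residualized
   against the realized plot-level design (and rescaled to sd σ_S). A
   single finite draw of effects otherwise carries chance correlation with,
   say, ln distance (expected |r| ≈ 0.07 over 216 plots, concentrated on
   ~85 transects), which shifts that plot-covariate's coefficient
   identically in all three periods and defeats any single-run coverage
   check.

Measurement error is a separate, explicit operation: Normal diameter noise
(default sd 1 mm, producing the realistic share of small negative computed
growths), rare gross recording errors (default 0.2% of trees) that exceed
the outlier limits, and missing diameters (default 0.2%) to exercise
imputation. The pipeline applies it by default; the recovery studies fit
the error-free diameters because their question is matched-scale
coverage, not robustness to noise.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatial structure beyond the subplot grid (no
landslide geometry, no within-plot coordinates), weather/pathogen
disturbance cycles, species mixtures, growth model misspecification
(real growth is not log-linear), diameter-dependent measurement error, or
plot effects genuinely correlated with covariates. On real data the
endogeneity mechanisms excluded by design above are live concerns and the
coefficients should be read accordingly.

## Validation studies (what the tests and `scripts/acceptance.py` compute)

* **Grid oracle**: an intercept-only, no-random-effect sub-model on 200
  simulated observations, compared with a 1001-point brute-force grid
  posterior over logit ∈ [−2, 8]; posterior means agree within 0.05
  logits and sds within 10%.
* **Recovery study**: full 216-plot design, truth = the default
  coefficients, desk-scale MCMC; coverage of the 37 true parameters
  (12 coefficients × 3 periods + σ_S) by their 95% credible intervals is
  ≥ 90% (measured: 35/37 at the default seed).
* **Calibration**: over 20 small simulated forests (24 plots), the 95%
  interval for the pre-earthquake intercept covers the truth 18/20 times.
* **Selection direction**: at ~5,000 observations (60 plots), data with
  the strong default growth effects put all four previous-growth models
  more than 10 WAIC units ahead of the base model in ≥ 4/5 seeds; data
  with all growth coefficients zero keep the base model within 10 WAIC of
  the best in ≥ 4/5 seeds.
* **Curve shape**: on the recovery fit, predicted survival is
  nondecreasing in previous growth at 800/1000/1200 m in periods 1 and 3
  whenever every posterior draw has a positive growth slope there (the
  slope is linear on the logit scale, so this is exact per draw; the test
  verifies the posterior mean curve numerically).

Problem sizes (plots, observations, chain lengths) for these studies were
chosen as the smallest at which the checks are statistically meaningful;
all are configurable upward to the archival protocol.

## Known limitations

* The annual-survival construction assumes constant hazard within an
  interval; period boundaries must coincide with measurement years.
* One shared plot effect across periods cannot express plots whose quality
  changed (e.g. landslide-struck plots post-1993); on real data that
  variance lands partly in the period-2 distance and landform effects.
* The sampler is exact but not gradient-based; at far larger designs
  (10× more parameters) an HMC backend behind the same `fit` contract
  would be the natural replacement.
* Printed survival probabilities at "covariate zero" are intercept
  transforms, not population averages; averaging conventions differ and
  the package reports the logit-scale intercepts as primary.
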