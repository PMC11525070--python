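"""Simulation-based validation of the whole pipeline.

These routines regenerate synthetic data under known truth, refit the
model, and measure how faithfully the machinery recovers what it should:
an intercept-only posterior against a brute-force grid, coefficient
coverage at the full study design, WAIC's ability to detect (or correctly
not detect) growth effects, and the monotonicity of the growth-survival
curves. They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    BayesianTreeSurvival,
    ModelCoefficients,
    ModelSpec,
    PosteriorFit,
    predict_survival_curve,
)
from .prepare import assemble_observations
from .selection import build_candidate_set, compute_waic
from .synthetic import SimulationConfig, default_true_coefficients, simulate_forest

#: Desk-scale MCMC protocol used for the full-design recovery study.
DESK_MCMC = {"chains": 3, "iterations": 6000, "burn_in": 1000, "thin": 3}

#: Reduced protocol for the many fits of the model-selection study.
REDUCED_MCMC = {"chains": 3, "iterations": 900, "burn_in": 300, "thin": 3}

#: Coefficient base names of the selected model (one value per period each).
RECOVERY_PARAMS = [
    "mu", "gamma_y", "gamma_y2", "gamma_bas", "gamma_bas_x_ele",
    "gamma_g", "gamma_g_x_ele", "gamma_g1",
    "gamma_avp", "gamma_li", "gamma_ele", "gamma_dist",
]


def intercept_only_observations(
    seed: int = 42, n: int = 200, true_logit: float = 3.2
) -> pd.DataFrame:
    """Simulated covariate-free observations for the grid-posterior check."""
    rng = np.random.default_rng(seed)
    dt = rng.choice([4.0, 5.0, 6.0], size=n)
    s = 1.0 / (1.0 + np.exp(-true_logit))
    out = (rng.random(n) < s**dt).astype(int)
    zeros = np.zeros(n)
    return pd.DataFrame(
        {
            "tree_id": [f"t{i}" for i in range(n)],
            "plot_id": "P1",
            "start_year": 1983,
            "end_year": 1987,
            "delta_t_years": dt,
            "period_index": 1,
            "outcome": out,
            "diameter_std": zeros,
            "diameter_sq_std": zeros,
            "local_ba_std": zeros,
            "growth_prev": zeros,
            "growth_lag": zeros,
            "soil_p_std": zeros,
            "landform_std": zeros,
            "elevation_std": zeros,
            "distance_std": zeros,
        }
    )


def grid_posterior(
    obs: pd.DataFrame, grid=None, prior_sd: float = 10.0
) -> tuple[float, float]:
    """Brute-force posterior mean and sd of an intercept-only model.

    Evaluates the annualized interval-survival likelihood and the
    Normal(0, prior_sd) prior on a fixed grid of logit values and
    normalizes -- an oracle independent of the MCMC code path.
    """
    grid = np.linspace(-2.0, 8.0, 1001) if grid is None else np.asarray(grid)
    dt = obs["delta_t_years"].to_numpy(float)
    out = obs["outcome"].to_numpy(int)
    logpost = np.empty_like(grid)
    for i, m in enumerate(grid):
        s = 1.0 / (1.0 + np.exp(-m))
        x = dt * np.log(s)
        terms = np.where(out == 1, x, np.log(-np.expm1(x)))
        logpost[i] = terms.sum() - m * m / (2.0 * prior_sd**2)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float((grid * w).sum())
    sd = float(np.sqrt(((grid - mean) ** 2 * w).sum()))
    return mean, sd


def intercept_grid_check(seed: int = 42, n: int = 200) -> dict:
    """MCMC vs grid posterior for the intercept-only sub-model."""
    obs = intercept_only_observations(seed=seed, n=n)
    spec = ModelSpec(
        include_prev_growth=False,
        include_lag_growth=False,
        include_prev_growth_x_elev=False,
        include_lag_growth_x_elev=False,
        include_base=False,
        include_plot_effect=False,
        name="intercept-only",
    )
    est = BayesianTreeSurvival(
        spec=spec, seed=seed, chains=3, iterations=3000, burn_in=500, thin=3
    )
    est.fit(obs)
    gm, gsd = grid_posterior(obs)
    mm = float(est.draws_["mu[1]"].mean())
    msd = float(est.draws_["mu[1]"].std(ddof=1))
    return {
        "mcmc_mean": mm,
        "grid_mean": gm,
        "mcmc_sd": msd,
        "grid_sd": gsd,
        "mean_abs_diff": abs(mm - gm),
        "sd_rel_diff": abs(msd - gsd) / gsd,
        "n": n,
    }


def recovery_study(
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    mcmc: dict | None = None,
) -> dict:
    """Simulate the full study design, refit, and measure coverage.

    Returns the coverage fraction of 95% credible intervals over all true
    coefficients of the selected model (12 coefficients x 3 periods plus
    the random-effect sd), along with the fit and observations for further
    checks.
    """
    cfg = sim_config or SimulationConfig()
    dataset = simulate_forest(cfg, seed=seed)
    obs, _ = assemble_observations(dataset.trees, dataset.plots)
    est = BayesianTreeSurvival(spec="selected", seed=seed, **(mcmc or DESK_MCMC))
    est.fit(obs)
    truth = dataset.truth

    n_inside = 0
    total = 0
    misses = []
    for name in RECOVERY_PARAMS:
        for p in (1, 2, 3):
            lo, hi = est.fit_.credible_interval(f"{name}[{p}]")
            t = truth.get(name, p)
            total += 1
            if lo <= t <= hi:
                n_inside += 1
            else:
                misses.append(f"{name}[{p}]")
    lo, hi = est.fit_.credible_interval("sigma_s")
    total += 1
    if lo <= truth.sigma_s <= hi:
        n_inside += 1
    else:
        misses.append("sigma_s")

    return {
        "coverage": n_inside / total,
        "n_inside": n_inside,
        "n_params": total,
        "misses": misses,
        "n_obs": len(obs),
        "max_rhat": float(np.nanmax(est.rhat_.to_numpy())),
        "fit": est.fit_,
        "observations": obs,
        "truth": truth,
    }


def null_growth_truth() -> ModelCoefficients:
    """The default truth with every growth coefficient removed (set to 0)."""
    t = default_true_coefficients()
    values = {
        k: v for k, v in t.values.items()
        if k not in ("gamma_g", "gamma_g_x_ele", "gamma_g1", "gamma_g1_x_ele")
    }
    return ModelCoefficients(values=values, sigma_s=t.sigma_s)


#: The four candidates containing previous growth, plus the base model.
_DIRECTION_MODELS = ["base", "prev", "prev+prevxele", "prev+lag", "selected"]


def selection_direction_study(
    scenario: str,
    seeds=(0, 1, 2, 3, 4),
    n_plots: int = 60,
    n_transects: int = 24,
    mcmc: dict | None = None,
) -> pd.DataFrame:
    """WAIC margins of previous-growth models over the base model.

    ``scenario`` is "strong" (truth = the default coefficients, with their
    strong previous-growth effects) or "null" (all growth coefficients 0).
    One row per seed with the WAIC of each candidate minus the best, and
    the margin by which the worst previous-growth model still beats base.
    """
    if scenario == "strong":
        truth = default_true_coefficients()
        seed_base = 100
    elif scenario == "null":
        truth = null_growth_truth()
        seed_base = 200
    else:
        raise ValueError("scenario must be 'strong' or 'null'")
    specs = {s.name: s for _, s in build_candidate_set()}
    mcmc = mcmc or REDUCED_MCMC

    rows = []
    for seed in seeds:
        cfg = SimulationConfig(
            seed=seed_base + seed,
            n_plots=n_plots,
            n_transects=n_transects,
            true_coefficients=truth,
        )
        dataset = simulate_forest(cfg)
        obs, _ = assemble_observations(dataset.trees, dataset.plots)
        waics = {}
        for name in _DIRECTION_MODELS:
            est = BayesianTreeSurvival(spec=specs[name], seed=seed, **mcmc)
            est.fit(obs)
            waics[name] = compute_waic(est.fit_).waic
        best = min(waics.values())
        growth_models = [m for m in _DIRECTION_MODELS if m != "base"]
        min_margin = min(waics["base"] - waics[m] for m in growth_models)
        rows.append(
            {
                "seed": seed,
                "n_obs": len(obs),
                **{f"delta_{k}": v - best for k, v in waics.items()},
                "base_minus_best": waics["base"] - best,
                "min_growth_margin": min_margin,
            }
        )
    return pd.DataFrame(rows)


def curve_monotonicity_check(
    fit: PosteriorFit,
    observations: pd.DataFrame,
    periods=(1, 3),
    elevations=(800.0, 1000.0, 1200.0),
    n_grid: int = 40,
) -> dict:
    """Check growth-survival curves rise with growth when the slope sign does.

    For each period x elevation, if every posterior draw satisfies
    gamma_G + gamma_Gxele * ele_std > 0, the posterior-mean curve must be
    nondecreasing across the central-95% growth grid.
    """
    from .model import central_growth_bounds

    checked = 0
    monotone = 0
    for period in periods:
        for elev in elevations:
            ele_std = (elev - 1000.0) / 100.0
            slope = (
                fit.coefficient_draws("gamma_g", period)
                + fit.coefficient_draws("gamma_g_x_ele", period) * ele_std
            )
            if not (slope > 0).all():
                continue
            lo, hi = central_growth_bounds(observations, period, elev)
            grid = np.linspace(lo, hi, n_grid)
            curve = predict_survival_curve(fit, period, elev, grid)
            checked += 1
            if (np.diff(curve["survival_mean"].to_numpy()) >= -1e-12).all():
                monotone += 1
    return {
        "checked": checked,
        "monotone": monotone,
        "fraction": monotone / checked if checked else float("nan"),
    }
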