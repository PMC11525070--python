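"""Posterior summary tables, growth-survival curve exports, basal-area
series, and the end-to-end pipeline.

Everything written here is recomputable from the stored fit container:
re-summarizing a saved fit reproduces summary.csv exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    ALIVE,
    PLOT_AREA_HA,
    MeasurementSchedule,
    basal_area_m2,
    read_plot_table,
    read_tree_table,
    write_observations,
    write_plot_table,
    write_tree_table,
)
from .model import (
    ELEVATION_CLASSES,
    PERIODS,
    BayesianTreeSurvival,
    PosteriorFit,
    predict_survival_curve,
)
from .prepare import assemble_observations, clean_remeasurements
from .selection import select_models
from .synthetic import SimulationConfig, apply_measurement_error, simulate_forest

#: Posterior-summary row registry: (draw column, symbol, description).
SUMMARY_REGISTRY = [
    ("mu[1]", "muS_1", "Mean survival pre-earthquake (logit scale)"),
    ("mu[2]", "muS_2", "Mean survival 0-5 years post-earthquake (logit scale)"),
    ("mu[3]", "muS_3", "Mean survival 5+ years post-earthquake (logit scale)"),
    ("sigma_s", "sigmaS", "SD of plot-level random effect"),
    ("gamma_y[1]", "gamma_y_1", "Pre-earthquake linear effect of diameter"),
    ("gamma_y2[1]", "gamma_y2_1", "Pre-earthquake quadratic effect of diameter"),
    ("gamma_y[2]", "gamma_y_2", "0-5 years post-earthquake linear effect of diameter"),
    ("gamma_y2[2]", "gamma_y2_2", "0-5 years post-earthquake quadratic effect of diameter"),
    ("gamma_y[3]", "gamma_y_3", "5+ years post-earthquake linear effect of diameter"),
    ("gamma_y2[3]", "gamma_y2_3", "5+ years post-earthquake quadratic effect of diameter"),
    ("gamma_bas[1]", "gamma_bas_1", "Pre-earthquake effect of basal area"),
    ("gamma_bas[2]", "gamma_bas_2", "0-5 years post-earthquake effect of basal area"),
    ("gamma_bas[3]", "gamma_bas_3", "5+ years post-earthquake effect of basal area"),
    ("gamma_bas_x_ele[1]", "gamma_basxele_1", "Change of basal-area effect with elevation, pre-earthquake"),
    ("gamma_bas_x_ele[2]", "gamma_basxele_2", "Change of basal-area effect with elevation, 0-5 years post-earthquake"),
    ("gamma_bas_x_ele[3]", "gamma_basxele_3", "Change of basal-area effect with elevation, 5+ years post-earthquake"),
    ("gamma_g[1]", "gamma_G_1", "Pre-earthquake effect of previous growth"),
    ("gamma_g[2]", "gamma_G_2", "0-5 years post-earthquake effect of previous growth"),
    ("gamma_g[3]", "gamma_G_3", "5+ years post-earthquake effect of previous growth"),
    ("gamma_g_x_ele[1]", "gamma_Gxele_1", "Change of previous-growth effect with elevation, pre-earthquake"),
    ("gamma_g_x_ele[2]", "gamma_Gxele_2", "Change of previous-growth effect with elevation, 0-5 years post-earthquake"),
    ("gamma_g_x_ele[3]", "gamma_Gxele_3", "Change of previous-growth effect with elevation, 5+ years post-earthquake"),
    ("gamma_g1[1]", "gamma_G1_1", "Pre-earthquake effect of lagged growth"),
    ("gamma_g1[2]", "gamma_G1_2", "0-5 years post-earthquake effect of lagged growth"),
    ("gamma_g1[3]", "gamma_G1_3", "5+ years post-earthquake effect of lagged growth"),
    ("gamma_g1_x_ele[1]", "gamma_G1xele_1", "Change of lagged-growth effect with elevation, pre-earthquake"),
    ("gamma_g1_x_ele[2]", "gamma_G1xele_2", "Change of lagged-growth effect with elevation, 0-5 years post-earthquake"),
    ("gamma_g1_x_ele[3]", "gamma_G1xele_3", "Change of lagged-growth effect with elevation, 5+ years post-earthquake"),
    ("gamma_avp[1]", "gamma_avP_1", "Pre-earthquake effect of soil-available P"),
    ("gamma_avp[2]", "gamma_avP_2", "0-5 years post-earthquake effect of soil-available P"),
    ("gamma_avp[3]", "gamma_avP_3", "5+ years post-earthquake effect of soil-available P"),
    ("gamma_li[1]", "gamma_LI_1", "Pre-earthquake effect of landform index"),
    ("gamma_li[2]", "gamma_LI_2", "0-5 years post-earthquake effect of landform index"),
    ("gamma_li[3]", "gamma_LI_3", "5+ years post-earthquake effect of landform index"),
    ("gamma_ele[1]", "gamma_ele_1", "Pre-earthquake effect of elevation"),
    ("gamma_ele[2]", "gamma_ele_2", "0-5 years post-earthquake effect of elevation"),
    ("gamma_ele[3]", "gamma_ele_3", "5+ years post-earthquake effect of elevation"),
    ("gamma_dist[1]", "gamma_dist_1", "Pre-earthquake effect of distance from epicentre"),
    ("gamma_dist[2]", "gamma_dist_2", "0-5 years post-earthquake effect of distance from epicentre"),
    ("gamma_dist[3]", "gamma_dist_3", "5+ years post-earthquake effect of distance from epicentre"),
]


def summarize_posterior(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior summary table: one row per parameter in registry order.

    Columns: parameter symbol, description, posterior mean, sd and the
    empirical 2.5/97.5 percentiles; a final row summarizes the deviance.
    Parameters absent from the fitted model are skipped.
    """
    from .selection import deviance_draws

    rows = []
    for col, symbol, desc in SUMMARY_REGISTRY:
        if col not in fit.draws.columns:
            continue
        v = fit.draws[col].to_numpy()
        rows.append(
            {
                "parameter": symbol,
                "description": desc,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975)),
            }
        )
    d = deviance_draws(fit)
    rows.append(
        {
            "parameter": "deviance",
            "description": "Model deviance (-2 log-likelihood)",
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "q2.5": float(np.quantile(d, 0.025)),
            "q97.5": float(np.quantile(d, 0.975)),
        }
    )
    return pd.DataFrame(rows)


def basal_area_series(trees, plots, schedule: MeasurementSchedule | None = None) -> pd.DataFrame:
    """Mean (+/- SE) per-plot basal area (m2/ha) at each measurement year.

    Per plot and year, basal area sums the cross-sections of living trees
    over the 0.04 ha plot; the SE is sd/sqrt(n_plots) across plots (plots
    with no living trees contribute 0).
    """
    schedule = schedule or MeasurementSchedule.default()
    plot_ids = [p.plot_id for p in plots]
    idx = {pid: i for i, pid in enumerate(plot_ids)}
    ba = np.zeros((len(plot_ids), len(schedule.years)))
    for t in trees:
        if t.plot_id not in idx:
            continue
        for j, year in enumerate(schedule.years):
            if t.status.get(year) == ALIVE:
                d = t.diameters.get(year)
                if d is not None:
                    ba[idx[t.plot_id], j] += basal_area_m2(d)
    ba /= PLOT_AREA_HA
    n = len(plot_ids)
    return pd.DataFrame(
        {
            "year": schedule.years,
            "mean_ba": ba.mean(axis=0),
            "se_ba": ba.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "n_plots": n,
        }
    )


def export_survival_curves(
    fit: PosteriorFit,
    observations: pd.DataFrame,
    elevations=(800.0, 1000.0, 1200.0),
    n_grid: int = 50,
) -> pd.DataFrame:
    """Growth-survival curves per period x elevation, trimmed to the
    central 95% of observed previous growth in each period x elevation
    class."""
    frames = []
    for period in PERIODS:
        if (observations["period_index"] == period).sum() == 0:
            continue
        for elev in elevations:
            from .model import central_growth_bounds

            lo, hi = central_growth_bounds(observations, period, elev)
            grid = np.linspace(lo, hi, n_grid)
            cur = predict_survival_curve(fit, period, elev, grid)
            cur.insert(0, "elevation_m", elev)
            cur.insert(0, "period_index", period)
            frames.append(cur)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute simulate (optional) -> prepare -> fit -> select -> report.

    ``config`` keys::

        data:
          synthetic: {<SimulationConfig overrides>}   # or
          trees: trees.csv
          plots: plots.csv
        measurement_error: true       # synthetic data only
        model: selected | full | base
        mcmc: {chains, iterations, burn_in, thin}
        select: false                 # fit all nine candidates and rank
        seed: 0

    Writes trees.csv/plots.csv (synthetic), observations.csv, fit.nc,
    summary.csv, curves.csv, series.csv, optionally ranking.csv, an
    exclusions.csv audit log, and manifest.json. Any stage failure raises
    :class:`PipelineError` naming the stage; partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    schedule = MeasurementSchedule.default()

    stage = "simulate"
    try:
        data_cfg = config.get("data", {"synthetic": {}})
        if "synthetic" in data_cfg:
            sim_cfg = SimulationConfig(**{"seed": seed, **data_cfg["synthetic"]})
            dataset = simulate_forest(sim_cfg)
            if config.get("measurement_error", True):
                dataset = apply_measurement_error(
                    dataset,
                    sim_cfg.measurement_error_sd_mm,
                    gross_error_rate=sim_cfg.gross_error_rate,
                    missing_rate=sim_cfg.missing_rate,
                )
            trees, plots = dataset.trees, dataset.plots
            write_tree_table(trees, out / "trees.csv")
            write_plot_table(plots, out / "plots.csv")
            truth = {
                "sigma_s": dataset.truth.sigma_s,
                **{k: list(v) for k, v in dataset.truth.values.items()},
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=1))
        else:
            stage = "load"
            trees = read_tree_table(data_cfg["trees"], schedule)
            plots = read_plot_table(data_cfg["plots"])
        manifest["stages"].append(stage)
        manifest["n_trees"] = len(trees)
        manifest["n_plots"] = len(plots)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    stage = "prepare"
    try:
        trees, clean_log = clean_remeasurements(trees, schedule)
        obs, assembly_log = assemble_observations(trees, plots, schedule)
        write_observations(obs, out / "observations.csv")
        pd.DataFrame(clean_log + assembly_log).to_csv(
            out / "exclusions.csv", index=False
        )
        manifest["stages"].append(stage)
        manifest["n_observations"] = int(len(obs))
        manifest["n_survival_intervals"] = len(schedule.survival_intervals)
        manifest["n_periods"] = len(set(p for _, _, p in schedule.survival_intervals))
        manifest["n_exclusions"] = len(clean_log) + len(assembly_log)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    stage = "fit"
    try:
        est = BayesianTreeSurvival(
            spec=config.get("model", "selected"),
            seed=seed,
            **config.get("mcmc", {}),
        )
        est.fit(obs)
        fit = est.fit_
        fit.to_netcdf(out / "fit.nc")
        manifest["stages"].append(stage)
        manifest["n_draws"] = fit.n_draws
        manifest["max_rhat"] = float(np.nanmax(fit.rhat.to_numpy()))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    if config.get("select", False):
        stage = "select"
        try:
            ranking = select_models(obs, mcmc=config.get("mcmc", {}), seed=seed)
            ranking.to_csv(out / "ranking.csv", index=False)
            manifest["stages"].append(stage)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    stage = "report"
    try:
        summarize_posterior(fit).to_csv(out / "summary.csv", index=False)
        export_survival_curves(fit, obs).to_csv(out / "curves.csv", index=False)
        basal_area_series(trees, plots, schedule).to_csv(
            out / "series.csv", index=False
        )
        manifest["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
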