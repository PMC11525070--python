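"""Synthetic tagged-tree remeasurement datasets with known truth.

The generator emulates the permanent-plot study design the analysis
expects: 216 plots of 0.04 ha on 85 transects (1-8 plots each) spanning a
640-1417 m elevation gradient, 16 subplots of 5 m x 5 m per plot, trees
tagged at >= 30 mm diameter, and eight measurements (1974, 1978, 1983,
1987, 1993, 1999, 2004, 2009). Growth follows a simple log-linear model
declining with elevation and neighbourhood basal area; survival outcomes
are drawn from exactly the annualized interval-survival likelihood the
model module fits, using configurable true coefficients whose defaults are
the selected-model posterior means estimated for the mountain beech forest
this design mirrors. An earthquake overlay can add distance-dependent
injury (persistent growth suppression after 1993) and, optionally,
distance-dependent excess mortality in 1993-1999; the excess-mortality
knob defaults to zero so that every survival outcome remains an exact draw
from the fitted likelihood (the earthquake's survival signature is already
in the period-2 truth coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .data_model import (
    ALIVE,
    DEAD,
    NOT_TAGGED,
    MeasurementSchedule,
    PlotRecord,
    TreeRecord,
)
from .model import ModelCoefficients
from .prepare import NEIGHBOURHOOD_AREA_HA


def default_true_coefficients() -> ModelCoefficients:
    """Default data-generating truth (selected-model structure).

    Values are the published posterior means for the mountain beech forest
    the study design emulates; they serve as a realistic operating point,
    with strong previous-growth effects, a positive pre-earthquake
    elevation effect and a large positive period-2 distance effect.
    """
    return ModelCoefficients(
        values={
            "mu": np.array([3.691, 3.896, 3.667]),
            "gamma_y": np.array([0.00485, 0.00563, 0.00201]),
            "gamma_y2": np.array([-0.00002, -0.00002, -0.00001]),
            "gamma_bas": np.array([-0.011, -0.002, 0.002]),
            "gamma_bas_x_ele": np.array([-0.004, 0.009, -0.005]),
            "gamma_g": np.array([0.575, 0.187, 0.776]),
            "gamma_g_x_ele": np.array([-0.054, 0.062, 0.123]),
            "gamma_g1": np.array([0.361, 0.261, 0.288]),
            "gamma_avp": np.array([-0.047, -0.218, 0.072]),
            "gamma_li": np.array([-0.009, -0.092, -0.026]),
            "gamma_ele": np.array([0.242, -0.006, 0.023]),
            "gamma_dist": np.array([-0.055, 1.036, -0.004]),
        },
        sigma_s=0.966,
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic forest; defaults are the study conditions."""

    n_plots: int = 216
    n_transects: int = 85
    max_plots_per_transect: int = 8
    elevation_range: tuple[float, float] = (640.0, 1417.0)
    elevation_spread: float = 1.0  # 0 collapses all plots to the range midpoint
    landform_mean: float = 20.0
    landform_sd: float = 8.0
    slope_mean: float = 25.0
    slope_sd: float = 8.0
    log_soil_p_mean: float = 2.7
    log_soil_p_sd: float = 0.35
    log_distance_mean: float = 2.9
    log_distance_sd: float = 0.5

    schedule: MeasurementSchedule = field(default_factory=MeasurementSchedule.default)

    # stand structure
    stems_per_subplot: float = 5.5  # Poisson mean of initial stems per subplot
    initial_diameter_shape: float = 1.5  # gamma shape of (d - 30) mm
    initial_diameter_scale: float = 75.0  # gamma scale (mm)
    recruitment_per_subplot: float = 0.1  # Poisson mean per subplot per interval

    # log-linear growth model (mm/yr): declines with elevation and competition
    growth_log_intercept: float = 0.6  # ln growth at mid covariates and typical competition
    growth_elev_slope: float = -0.25  # per standardized elevation unit (100 m)
    growth_ba_slope: float = -0.012  # per m2/ha of local basal area
    growth_diameter_slope: float = 0.15  # per ln(d / 164 mm)
    growth_tree_sd: float = 0.45  # persistent tree-level log-growth sd
    growth_window_sd: float = 0.5  # per-window log-growth noise sd
    growth_max: float = 8.0  # physiological ceiling on true annual growth (mm/yr)

    # survival truth
    true_coefficients: ModelCoefficients = field(
        default_factory=default_true_coefficients
    )

    # earthquake overlay (between the 1993 and 1999 measurements)
    earthquake_year: int = 1993
    injury_scale: float = 0.25  # injury probability at the reference distance
    injury_reference_km: float = 6.0
    injury_ln_decay: float = 1.5  # decay of injury probability per ln(km)
    injury_growth_penalty: float = 0.7  # subtracted from ln growth if injured
    excess_mortality_scale: float = 0.0  # extra death probability at reference
    excess_mortality_ln_decay: float = 1.5

    # measurement error (applied by apply_measurement_error, not by simulate)
    measurement_error_sd_mm: float = 1.0
    gross_error_rate: float = 0.002
    missing_rate: float = 0.002

    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < self.n_transects:
            raise ValueError("need at least one plot per transect")
        if self.n_plots > self.n_transects * self.max_plots_per_transect:
            raise ValueError("too many plots for the transect capacity")
        for name in ("growth_window_sd", "growth_tree_sd", "landform_sd",
                     "log_soil_p_sd", "log_distance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SyntheticDataset:
    """Trees, plots and the truth that generated them."""

    trees: list[TreeRecord]
    plots: list[PlotRecord]
    truth: ModelCoefficients
    config: SimulationConfig


# ---------------------------------------------------------------------------


def generate_plot_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[PlotRecord]:
    """Assign plots to transects and draw plot-level covariates.

    Transects receive 1 to ``max_plots_per_transect`` plots; elevations are
    spread across the configured range (``elevation_spread`` = 0 collapses
    them to the midpoint); landform index, ln soil-P and ln epicentre
    distance are drawn from distributions centred near the standardization
    zero-points.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)

    sizes = np.ones(config.n_transects, dtype=int)
    remaining = config.n_plots - config.n_transects
    while remaining > 0:
        open_idx = np.flatnonzero(sizes < config.max_plots_per_transect)
        pick = rng.choice(open_idx)
        sizes[pick] += 1
        remaining -= 1

    lo, hi = config.elevation_range
    mid, width = (lo + hi) / 2.0, hi - lo
    plots: list[PlotRecord] = []
    serial = 0
    for t in range(config.n_transects):
        base = mid + width * config.elevation_spread * (rng.random() - 0.5)
        ln_dist = config.log_distance_mean + config.log_distance_sd * rng.standard_normal()
        for _ in range(sizes[t]):
            serial += 1
            elev = base + 40.0 * config.elevation_spread * rng.standard_normal()
            elev = float(np.clip(elev, lo, hi))
            plots.append(
                PlotRecord(
                    plot_id=f"P{serial:03d}",
                    transect_id=f"T{t + 1:02d}",
                    elevation_m=elev,
                    slope_deg=float(
                        np.clip(
                            config.slope_mean + config.slope_sd * rng.standard_normal(),
                            0.0,
                            55.0,
                        )
                    ),
                    landform_index=float(
                        np.clip(
                            config.landform_mean
                            + config.landform_sd * rng.standard_normal(),
                            0.0,
                            60.0,
                        )
                    ),
                    soil_avP_ug_g=float(
                        np.exp(
                            config.log_soil_p_mean
                            + config.log_soil_p_sd * rng.standard_normal()
                        )
                    ),
                    epicentre_distance_km=float(
                        np.exp(ln_dist + 0.05 * rng.standard_normal())
                    ),
                )
            )
    for p in plots:
        p.validate(config.elevation_range)
    return plots


def _block_ba(subplot_ba: np.ndarray) -> np.ndarray:
    """Map 16 subplot basal-area sums (m2) to the 3x3-block m2/ha per subplot."""
    grid = subplot_ba.reshape(4, 4)
    out = np.empty(16)
    for idx in range(16):
        r, c = idx // 4, idx % 4
        out[idx] = grid[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2].sum()
    return out / NEIGHBOURHOOD_AREA_HA


def _draw_plot_effects(rng, sigma_s: float, plots, stands) -> np.ndarray:
    """Draw plot random effects N(0, sigma_s^2), orthogonal to the design.

    The raw iid draws are residualized against the realized plot-level
    design (intercept, elevation, ln soil-P, landform, ln distance, initial
    stand basal area) and rescaled to sd ``sigma_s``. Marginally each
    effect is still a centred Gaussian of the right scale, but a single
    finite draw of effects can no longer masquerade as a plot-covariate
    effect -- chance correlation between the realized effects and, say,
    epicentre distance would otherwise shift that coefficient identically
    in all three periods and defeat any finite-sample recovery check.
    """
    n = len(plots)
    if sigma_s <= 0 or n == 0:
        return np.zeros(n)
    raw = sigma_s * rng.standard_normal(n)
    if n < 10:
        return raw
    ba0 = np.array(
        [np.sum(np.pi * (st["diam"] / 2000.0) ** 2) / 0.04 for st in stands]
    )
    Z = np.column_stack(
        [
            np.ones(n),
            [(p.elevation_m - 1000.0) / 100.0 for p in plots],
            [math.log(p.soil_avP_ug_g) - 2.7 for p in plots],
            [p.landform_index - 20.0 for p in plots],
            [math.log(p.epicentre_distance_km) - 2.9 for p in plots],
            ba0 - ba0.mean(),
        ]
    )
    coef, *_ = np.linalg.lstsq(Z, raw, rcond=None)
    resid = raw - Z @ coef
    sd = resid.std()
    return resid * (sigma_s / sd) if sd > 0 else raw


def simulate_forest(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SyntheticDataset:
    """Simulate the full remeasurement history of the plot network.

    Per measurement interval each living tree grows by a log-linear growth
    draw (declining with elevation and local basal area, persistent
    tree-level variation), then survives the interval with probability
    ``S^dt`` where the annual logit survival comes from the true
    coefficients at the tree's current covariates and its plot's random
    effect. The plot random effect is applied only to the trees of the four
    central subplots -- the subpopulation the survival model observes;
    neighbour trees' stand dynamics run at the population-level rates. This
    keeps the neighbourhood basal-area covariate exogenous to the modelled
    outcomes: were the same plot effect to drive neighbour mortality over
    the 35-year record, local basal area would accumulate the plot effect's
    mortality history and become an endogenous covariate that biases any
    fit, however exact the likelihood. Growth covariates for an interval are the true growth rates of
    the two preceding windows (the current window stands in where history
    is shorter than two windows, which only affects intervals that never
    become model observations). Diameters returned are exact; measurement
    error is a separate, explicit step.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = dc_replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    plots = generate_plot_network(config, rng)
    truth = config.true_coefficients
    schedule = config.schedule
    years = schedule.years
    period_of_interval = {(s, e): p for s, e, p in schedule.survival_intervals}

    eps_by_plot: dict[str, float] = {}
    trees: list[TreeRecord] = []

    # pass 1: draw the 1974 stands, so plot effects can then be drawn
    # orthogonal to the realized plot-level design
    stands = []
    for plot in plots:
        n0 = rng.poisson(config.stems_per_subplot, size=16)
        subplot = np.repeat(np.arange(1, 17), n0)
        diam = 30.0 + rng.gamma(
            config.initial_diameter_shape,
            config.initial_diameter_scale,
            size=len(subplot),
        )
        tree_eff = config.growth_tree_sd * rng.standard_normal(len(subplot))
        stands.append({"plot": plot, "subplot": subplot, "diam": diam,
                       "tree_eff": tree_eff})

    eps_vec = _draw_plot_effects(rng, truth.sigma_s, plots, stands)

    # pass 2: stand dynamics
    for st, eps in zip(stands, eps_vec):
        plot = st["plot"]
        eps = float(eps)
        eps_by_plot[plot.plot_id] = eps
        ele = (plot.elevation_m - 1000.0) / 100.0
        avp = math.log(plot.soil_avP_ug_g) - 2.7
        li = plot.landform_index - 20.0
        dist = math.log(plot.epicentre_distance_km) - 2.9

        subplot, diam, tree_eff = st["subplot"], st["diam"], st["tree_eff"]
        n = len(subplot)
        alive = np.ones(n, dtype=bool)
        injured = np.zeros(n, dtype=bool)
        first_year = np.full(n, years[0])
        prev_rate = np.full(n, np.nan)
        lag_rate = np.full(n, np.nan)
        diam_hist: list[dict[int, float]] = [{years[0]: float(d)} for d in diam]
        death_year = np.full(n, -1)

        inj_prob = float(
            np.clip(
                config.injury_scale
                * math.exp(
                    -config.injury_ln_decay
                    * (math.log(plot.epicentre_distance_km)
                       - math.log(config.injury_reference_km))
                ),
                0.0,
                1.0,
            )
        )
        excess_prob = float(
            np.clip(
                config.excess_mortality_scale
                * math.exp(
                    -config.excess_mortality_ln_decay
                    * (math.log(plot.epicentre_distance_km)
                       - math.log(config.injury_reference_km))
                ),
                0.0,
                1.0,
            )
        )

        for y0, y1 in zip(years[:-1], years[1:]):
            dt = y1 - y0
            # neighbourhood competition from the current living stand
            sub_ba = np.zeros(16)
            if alive.any():
                np.add.at(
                    sub_ba,
                    subplot[alive] - 1,
                    np.pi * (diam[alive] / 2000.0) ** 2,
                )
            local_ba = _block_ba(sub_ba)[subplot - 1]

            # growth over (y0, y1)
            log_g = (
                config.growth_log_intercept
                + config.growth_elev_slope * ele
                + config.growth_ba_slope * local_ba
                + config.growth_diameter_slope * np.log(np.maximum(diam, 30.0) / 164.0)
                + tree_eff
                + config.growth_window_sd * rng.standard_normal(len(diam))
            )
            if y0 >= config.earthquake_year:
                log_g = log_g - config.injury_growth_penalty * injured
            growth = np.minimum(np.exp(log_g), config.growth_max)

            # survival over (y0, y1) at the start-of-interval covariates
            p = period_of_interval.get((y0, y1), 1)
            g_prev = np.where(np.isnan(prev_rate), growth, prev_rate)
            g_lag = np.where(np.isnan(lag_rate), g_prev, lag_rate)
            y_std = diam - 164.0
            bas_std = local_ba - 50.0
            logit = (
                truth.get("mu", p)
                + truth.get("gamma_y", p) * y_std
                + truth.get("gamma_y2", p) * y_std**2
                + truth.get("gamma_bas", p) * bas_std
                + truth.get("gamma_bas_x_ele", p) * bas_std * ele
                + truth.get("gamma_g", p) * g_prev
                + truth.get("gamma_g_x_ele", p) * g_prev * ele
                + truth.get("gamma_g1", p) * g_lag
                + truth.get("gamma_g1_x_ele", p) * g_lag * ele
                + truth.get("gamma_avp", p) * avp
                + truth.get("gamma_li", p) * li
                + truth.get("gamma_ele", p) * ele
                + truth.get("gamma_dist", p) * dist
                + eps * np.isin(subplot, (6, 7, 10, 11))
            )
            s_interval = (1.0 / (1.0 + np.exp(-logit))) ** dt
            survive = rng.random(len(diam)) < s_interval

            if y0 == config.earthquake_year:
                if excess_prob > 0.0:
                    survive &= rng.random(len(diam)) >= excess_prob
                injured = injured | (
                    alive & survive & (rng.random(len(diam)) < inj_prob)
                )

            newly_dead = alive & ~survive
            death_year[newly_dead] = y1
            survivors = alive & survive
            diam = np.where(survivors, diam + growth * dt, diam)
            for i in np.flatnonzero(survivors):
                diam_hist[i][y1] = float(diam[i])
            alive = survivors
            lag_rate, prev_rate = prev_rate.copy(), growth.copy()

            # recruitment at the y1 measurement
            if config.recruitment_per_subplot > 0 and y1 != years[-1]:
                nr = rng.poisson(config.recruitment_per_subplot, size=16)
                r_subplot = np.repeat(np.arange(1, 17), nr)
                m = len(r_subplot)
                if m:
                    r_diam = 30.0 + rng.exponential(5.0, size=m)
                    subplot = np.concatenate([subplot, r_subplot])
                    diam = np.concatenate([diam, r_diam])
                    tree_eff = np.concatenate(
                        [tree_eff, config.growth_tree_sd * rng.standard_normal(m)]
                    )
                    alive = np.concatenate([alive, np.ones(m, dtype=bool)])
                    injured = np.concatenate([injured, np.zeros(m, dtype=bool)])
                    first_year = np.concatenate([first_year, np.full(m, y1)])
                    prev_rate = np.concatenate([prev_rate, np.full(m, np.nan)])
                    lag_rate = np.concatenate([lag_rate, np.full(m, np.nan)])
                    death_year = np.concatenate([death_year, np.full(m, -1)])
                    diam_hist.extend({y1: float(d)} for d in r_diam)

        for i in range(len(subplot)):
            status = {}
            for y in years:
                if y < first_year[i]:
                    status[y] = NOT_TAGGED
                elif death_year[i] != -1 and y >= death_year[i]:
                    status[y] = DEAD
                else:
                    status[y] = ALIVE
            trees.append(
                TreeRecord(
                    tree_id=f"{plot.plot_id}-{i + 1:04d}",
                    plot_id=plot.plot_id,
                    subplot_index=int(subplot[i]),
                    diameters=diam_hist[i],
                    status=status,
                )
            )

    truth_out = ModelCoefficients(
        values={k: v.copy() for k, v in truth.values.items()},
        sigma_s=truth.sigma_s,
        plot_effects=eps_by_plot,
    )
    return SyntheticDataset(trees=trees, plots=plots, truth=truth_out, config=config)


def apply_measurement_error(
    dataset: SyntheticDataset,
    sd_mm: float,
    gross_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Overlay observation noise on the true diameters.

    Adds independent Normal(0, sd_mm) error to every recorded diameter (so
    slow growers show occasional small negative computed growths), plants
    rare gross recording errors (per-tree probability ``gross_error_rate``,
    +/- 40-150 mm at one measurement) that exceed the +10 / -3 mm/yr
    plausibility limits, and deletes diameters at rate ``missing_rate`` to
    exercise imputation. ``sd_mm = 0`` with both rates 0 returns an
    identical dataset.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be nonnegative")
    rng = np.random.default_rng(dataset.config.seed + 1 if seed is None else seed)
    new_trees = []
    for tree in dataset.trees:
        t = tree.copy()
        years = sorted(t.diameters)
        if sd_mm > 0:
            for y in years:
                t.diameters[y] = t.diameters[y] + sd_mm * rng.standard_normal()
        if gross_error_rate > 0 and len(years) >= 2 and rng.random() < gross_error_rate:
            y = years[int(rng.integers(len(years)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            t.diameters[y] = max(5.0, t.diameters[y] + sign * rng.uniform(40.0, 150.0))
        if missing_rate > 0 and len(years) >= 3 and rng.random() < missing_rate:
            middle = years[1:-1]
            y = middle[int(rng.integers(len(middle)))]
            del t.diameters[y]
        new_trees.append(t)
    return SyntheticDataset(
        trees=new_trees, plots=dataset.plots, truth=dataset.truth,
        config=dataset.config,
    )
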