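"""Turn raw remeasurement tables into model-ready survival observations.

The pipeline is: compute per-window annual growth rates, flag gross outliers
(> 10 or < -3 mm/yr), impute flagged/missing diameters from plot-level median
growth, compute neighbourhood local basal area, standardize covariates, and
assemble one observation per (tree alive at interval start, survival
interval) restricted to the four central subplots.

Growth windows for a survival interval starting at schedule year t are the
two measurement intervals immediately preceding t: *previous growth* over
(t-1, t) and *lagged growth* over (t-2, t-1) in schedule indices. For the
1983-1987 survival interval these are 1978-1983 and 1974-1978 respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import (
    ALIVE,
    CENTRAL_SUBPLOTS,
    DEAD,
    MeasurementSchedule,
    StandardizationConfig,
    TreeRecord,
    basal_area_m2,
    OBS_COLUMNS,
)

#: Outlier limits for annual diameter growth (mm/yr), strict inequalities.
GROWTH_UPPER_LIMIT = 10.0
GROWTH_LOWER_LIMIT = -3.0

#: Area (ha) of the 15 m x 15 m neighbourhood window (3x3 subplot block).
NEIGHBOURHOOD_AREA_HA = 0.0225


class ImputationError(ValueError):
    """Raised when a diameter cannot be imputed (no reliable anchor)."""


@dataclass(frozen=True)
class GrowthWindowPair:
    """The two growth windows feeding one survival interval.

    ``previous`` ends at the survival interval's start; ``lagged``
    immediately precedes ``previous``. Rates are mm/yr.
    """

    previous: tuple[int, int, float]
    lagged: tuple[int, int, float]


# ---------------------------------------------------------------------------
# Growth


def interval_growth(d_start: float, d_end: float, delta_t: float) -> float:
    """Annual diameter growth (mm/yr) over a window; negative values allowed.

    Small negative growths are genuine data (routine measurement error on a
    slow-growing species) and must be retained, not clipped.
    """
    if d_start is None or d_end is None or (
        isinstance(d_start, float) and math.isnan(d_start)
    ) or (isinstance(d_end, float) and math.isnan(d_end)):
        raise ImputationError("missing diameter: imputation required")
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return (d_end - d_start) / delta_t


def tree_window_rates(tree: TreeRecord, schedule: MeasurementSchedule) -> dict[tuple[int, int], float]:
    """Growth rate for every consecutive-measurement window with both diameters."""
    rates: dict[tuple[int, int], float] = {}
    yrs = schedule.years
    for y0, y1 in zip(yrs[:-1], yrs[1:]):
        d0, d1 = tree.diameters.get(y0), tree.diameters.get(y1)
        if d0 is not None and d1 is not None:
            rates[(y0, y1)] = (d1 - d0) / (y1 - y0)
    return rates


def flag_growth_outliers(rates_by_tree: dict) -> set:
    """Tree ids with any window rate strictly above 10 or below -3 mm/yr.

    Boundary values (exactly 10.0 or -3.0) are not flagged.
    """
    flagged = set()
    for tree_id, rates in rates_by_tree.items():
        vals = rates.values() if isinstance(rates, dict) else rates
        if any(r > GROWTH_UPPER_LIMIT or r < GROWTH_LOWER_LIMIT for r in vals):
            flagged.add(tree_id)
    return flagged


# ---------------------------------------------------------------------------
# Imputation


class PlotGrowthContext:
    """Plot-level growth summaries used to impute suspect diameters.

    For each measurement window and diameter tercile (terciles of the
    window-start diameters of the plot's reliable trees), holds the median
    annual growth rate. A suspect diameter is replaced by the nearest
    reliable measurement plus the tercile median growth over the gap.
    """

    def __init__(self, plot_trees, schedule: MeasurementSchedule):
        self.schedule = schedule
        self._windows: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        yrs = schedule.years
        for y0, y1 in zip(yrs[:-1], yrs[1:]):
            d0s, rates = [], []
            for t in plot_trees:
                d0, d1 = t.diameters.get(y0), t.diameters.get(y1)
                if d0 is None or d1 is None:
                    continue
                r = (d1 - d0) / (y1 - y0)
                if GROWTH_LOWER_LIMIT < r < GROWTH_UPPER_LIMIT:
                    d0s.append(d0)
                    rates.append(r)
            self._windows[(y0, y1)] = (np.asarray(d0s), np.asarray(rates))

    def median_rate(self, y0: int, y1: int, anchor_diameter: float) -> float:
        """Median growth (mm/yr) of same-tercile plot trees over [y0, y1]."""
        yrs = self.schedule.years
        i0, i1 = yrs.index(y0), yrs.index(y1)
        sub_rates = []
        for a, b in zip(yrs[i0:i1], yrs[i0 + 1 : i1 + 1]):
            d0s, rates = self._windows[(a, b)]
            if len(rates) == 0:
                continue
            if len(rates) >= 3:
                lo, hi = np.quantile(d0s, [1 / 3, 2 / 3])
                if anchor_diameter <= lo:
                    sel = d0s <= lo
                elif anchor_diameter <= hi:
                    sel = (d0s > lo) & (d0s <= hi)
                else:
                    sel = d0s > hi
                if sel.any():
                    rates = rates[sel]
            sub_rates.append(float(np.median(rates)))
        if not sub_rates:
            raise ImputationError(f"no reliable plot growth data over {y0}-{y1}")
        return float(np.mean(sub_rates))


def impute_diameter(tree: TreeRecord, year: int, context: PlotGrowthContext) -> float:
    """Diameter (mm) predicted for ``year`` from the nearest reliable anchor.

    The anchor is the closest other measurement of the tree (earlier
    preferred on ties); the prediction walks the plot x diameter-tercile
    median growth from the anchor to ``year``. Raises
    :class:`ImputationError` if the tree has no other measurement.
    """
    anchors = [y for y in tree.diameters if y != year and y not in tree.imputed_years]
    if not anchors:
        anchors = [y for y in tree.diameters if y != year]
    if not anchors:
        raise ImputationError(f"tree {tree.tree_id}: no anchor measurement for {year}")
    anchor = min(anchors, key=lambda y: (abs(y - year), y > year))
    d_anchor = tree.diameters[anchor]
    y0, y1 = (anchor, year) if anchor < year else (year, anchor)
    rate = context.median_rate(y0, y1, d_anchor)
    return d_anchor + rate * (year - anchor)


def clean_remeasurements(trees, schedule: MeasurementSchedule):
    """Impute outlier/missing diameters; exclude unresolvable trees.

    Returns ``(clean_trees, log)`` where ``log`` is a list of dicts, one per
    imputation or exclusion, so the cleaning is auditable on any dataset.
    Trees are never silently dropped.
    """
    by_plot: dict[str, list[TreeRecord]] = {}
    for t in trees:
        by_plot.setdefault(t.plot_id, []).append(t)

    out, log = [], []
    for plot_id, plot_trees in by_plot.items():
        context = PlotGrowthContext(plot_trees, schedule)
        for tree in plot_trees:
            tree = tree.copy()
            ok = True
            # Missing diameters at years the tree was alive/dead-recorded.
            for year in sorted(tree.status):
                if tree.status[year] == ALIVE and year not in tree.diameters:
                    try:
                        tree.diameters[year] = impute_diameter(tree, year, context)
                        tree.imputed_years.add(year)
                        log.append(
                            {"tree_id": tree.tree_id, "year": year,
                             "action": "imputed-missing",
                             "value": tree.diameters[year]}
                        )
                    except ImputationError as exc:
                        log.append(
                            {"tree_id": tree.tree_id, "year": year,
                             "action": "excluded", "reason": str(exc)}
                        )
                        ok = False
                        break
            if not ok:
                continue
            # Outlier windows: impute the most-implicated measurement year.
            for _attempt in range(len(schedule.years)):
                rates = tree_window_rates(tree, schedule)
                bad = {
                    w: r
                    for w, r in rates.items()
                    if r > GROWTH_UPPER_LIMIT or r < GROWTH_LOWER_LIMIT
                }
                if not bad:
                    break
                score: dict[int, int] = {}
                for (y0, y1) in bad:
                    score[y0] = score.get(y0, 0) + 1
                    score[y1] = score.get(y1, 0) + 1
                suspect = max(score, key=lambda y: (score[y], y))
                try:
                    tree.imputed_years.add(suspect)
                    tree.diameters[suspect] = impute_diameter(tree, suspect, context)
                    log.append(
                        {"tree_id": tree.tree_id, "year": suspect,
                         "action": "imputed-outlier",
                         "value": tree.diameters[suspect]}
                    )
                except ImputationError as exc:
                    log.append(
                        {"tree_id": tree.tree_id, "year": suspect,
                         "action": "excluded", "reason": str(exc)}
                    )
                    ok = False
                    break
            else:
                ok = False
                log.append(
                    {"tree_id": tree.tree_id, "action": "excluded",
                     "reason": "outlier growth not resolvable by imputation"}
                )
            if ok:
                out.append(tree)
    return out, log


# ---------------------------------------------------------------------------
# Neighbourhood competition


def _subplot_rc(subplot_index: int) -> tuple[int, int]:
    return (subplot_index - 1) // 4, (subplot_index - 1) % 4


def neighbourhood_subplots(subplot_index: int) -> frozenset[int]:
    """Subplot indices of the 3x3 block (15 m x 15 m) centred on a subplot.

    Blocks for edge subplots are truncated at the plot boundary; for the
    four central subplots the block lies wholly inside the plot.
    """
    r, c = _subplot_rc(subplot_index)
    cells = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < 4 and 0 <= cc < 4:
                cells.append(rr * 4 + cc + 1)
    return frozenset(cells)


def local_basal_area(plot_trees, subplot_index: int, year: int) -> float:
    """Local basal area (m2/ha) of living trees in the 15 m x 15 m window.

    Sums stem cross-sections of all trees alive at ``year`` whose subplot
    lies in the 3x3 block centred on ``subplot_index``, over 0.0225 ha.
    Dead trees contribute zero from the first measurement at which they are
    recorded dead.
    """
    block = neighbourhood_subplots(subplot_index)
    total = 0.0
    for t in plot_trees:
        if t.subplot_index not in block or t.status.get(year) != ALIVE:
            continue
        d = t.diameters.get(year)
        if d is not None:
            total += basal_area_m2(d)
    return total / NEIGHBOURHOOD_AREA_HA


# ---------------------------------------------------------------------------
# Standardization


def standardize(value, config: StandardizationConfig, covariate: str):
    """Map a raw covariate value onto its standardized model scale."""
    sc = config.scale_for(covariate)
    v = np.asarray(value, dtype=float)
    if sc.transform == "log":
        if np.any(v <= 0):
            raise ValueError(f"{covariate}: log transform needs positive values")
        v = np.log(v)
    out = (v - sc.zero_point) / sc.divisor
    return float(out) if np.ndim(value) == 0 else out


def unstandardize(value, config: StandardizationConfig, covariate: str):
    """Inverse of :func:`standardize`."""
    sc = config.scale_for(covariate)
    v = np.asarray(value, dtype=float) * sc.divisor + sc.zero_point
    if sc.transform == "log":
        v = np.exp(v)
    return float(v) if np.ndim(value) == 0 else v


class CovariateStandardizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer applying the fixed standardization constants.

    Unlike a data-driven scaler the constants are part of the study design
    (so coefficients are comparable across datasets); ``fit`` only validates
    columns. ``columns`` maps DataFrame column -> covariate name in the
    :class:`~beechsurv.data_model.StandardizationConfig`.
    """

    def __init__(self, columns: dict | None = None,
                 config: StandardizationConfig | None = None):
        self.columns = columns
        self.config = config

    def _resolved(self):
        cfg = self.config or StandardizationConfig()
        cols = self.columns or {
            "elevation_m": "elevation",
            "landform_index": "landform",
            "soil_avP_ug_g": "soil_p",
            "epicentre_distance_km": "distance",
        }
        return cols, cfg

    def fit(self, X: pd.DataFrame, y=None):
        cols, _ = self._resolved()
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        self.columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols, cfg = self._resolved()
        out = X.copy()
        for col, cov in cols.items():
            out[col] = standardize(X[col].to_numpy(), cfg, cov)
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols, cfg = self._resolved()
        out = X.copy()
        for col, cov in cols.items():
            out[col] = unstandardize(X[col].to_numpy(), cfg, cov)
        return out


# ---------------------------------------------------------------------------
# Observation assembly


def growth_windows(schedule: MeasurementSchedule, start_year: int) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """(previous, lagged) measurement windows for an interval starting at start_year."""
    i = schedule.years.index(start_year)
    if i < 2:
        return None
    yrs = schedule.years
    return (yrs[i - 1], yrs[i]), (yrs[i - 2], yrs[i - 1])


def assemble_observations(
    trees,
    plots,
    schedule: MeasurementSchedule | None = None,
    config: StandardizationConfig | None = None,
    restrict_central: bool = True,
):
    """Build the observations table: one row per eligible tree x interval.

    Eligibility: the tree is alive at the interval start, lies in one of the
    four central subplots (unless ``restrict_central`` is False), and has
    diameters at the three measurements bounding its previous and lagged
    growth windows. Trees alive at the start but unrecorded at the interval
    end are excluded (logged), not treated as dead. All plot trees (any
    subplot) contribute to neighbour basal area.

    Returns ``(observations DataFrame, exclusion log)``.
    """
    schedule = schedule or MeasurementSchedule.default()
    config = config or StandardizationConfig()
    plot_by_id = {p.plot_id: p for p in plots}
    trees_by_plot: dict[str, list[TreeRecord]] = {}
    for t in trees:
        trees_by_plot.setdefault(t.plot_id, []).append(t)

    plot_std: dict[str, dict[str, float]] = {}
    for p in plots:
        plot_std[p.plot_id] = {
            "soil_p_std": standardize(p.soil_avP_ug_g, config, "soil_p"),
            "landform_std": standardize(p.landform_index, config, "landform"),
            "elevation_std": standardize(p.elevation_m, config, "elevation"),
            "distance_std": standardize(p.epicentre_distance_km, config, "distance"),
        }

    rows, log = [], []
    for plot_id in sorted(trees_by_plot):
        if plot_id not in plot_by_id:
            log.append({"plot_id": plot_id, "action": "excluded",
                        "reason": "plot covariates missing"})
            continue
        plot_trees = trees_by_plot[plot_id]
        pstd = plot_std[plot_id]
        ba_cache: dict[tuple[int, int], float] = {}
        for start, end, period in schedule.survival_intervals:
            windows = growth_windows(schedule, start)
            if windows is None:
                continue
            (p0, p1), (l0, l1) = windows
            for tree in sorted(plot_trees, key=lambda t: t.tree_id):
                if restrict_central and tree.subplot_index not in CENTRAL_SUBPLOTS:
                    continue
                if not tree.alive_at(start):
                    continue
                d_now = tree.diameters.get(start)
                d_p0 = tree.diameters.get(p0)
                d_l0 = tree.diameters.get(l0)
                if d_now is None or d_p0 is None or d_l0 is None:
                    continue  # growth windows not computable (e.g., recruit)
                status_end = tree.status.get(end)
                if status_end not in (ALIVE, DEAD):
                    log.append({"tree_id": tree.tree_id, "interval": (start, end),
                                "action": "excluded",
                                "reason": "status unrecorded at interval end"})
                    continue
                key = (tree.subplot_index, start)
                if key not in ba_cache:
                    ba_cache[key] = local_basal_area(plot_trees, tree.subplot_index, start)
                d_std = standardize(d_now, config, "diameter")
                rows.append(
                    {
                        "tree_id": tree.tree_id,
                        "plot_id": plot_id,
                        "start_year": start,
                        "end_year": end,
                        "delta_t_years": float(end - start),
                        "period_index": period,
                        "outcome": 1 if status_end == ALIVE else 0,
                        "diameter_std": d_std,
                        "diameter_sq_std": d_std * d_std,
                        "local_ba_std": standardize(ba_cache[key], config, "basal_area"),
                        "growth_prev": interval_growth(d_p0, d_now, p1 - p0),
                        "growth_lag": interval_growth(d_l0, d_p0, l1 - l0),
                        **pstd,
                    }
                )
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    obs = obs.sort_values(["start_year", "plot_id", "tree_id"], kind="mergesort")
    return obs.reset_index(drop=True), log
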