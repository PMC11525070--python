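"""Domain types and tabular I/O for tagged-tree remeasurement data.

The package works with three plain-CSV tables (documented in
``schemas/tables.yaml`` shipped with the package):

* ``trees.csv`` — long form, one row per tree x measurement
  (tree_id, plot_id, subplot, year, diameter_mm, status);
* ``plots.csv`` — one row per plot with its constant covariates;
* ``observations.csv`` — one row per tree x survival interval, the
  model-ready unit of analysis.

Diameters are millimetres at 1.4 m height; trees enter the record at
>= 30 mm (the tagging threshold). Death is absorbing: a tree recorded
dead stays dead (or drops out of the table) at all later measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ALIVE = "alive"
DEAD = "dead"
NOT_TAGGED = "not-yet-tagged"
_STATUSES = {ALIVE, DEAD, NOT_TAGGED}

#: Minimum diameter (mm) at which a stem is tagged.
MIN_TAG_DIAMETER_MM = 30.0

#: Plot area in hectares (20 m x 20 m).
PLOT_AREA_HA = 0.04

#: Subplot indices (1-16, row-major on the 4x4 grid) of the four central
#: 5 m x 5 m subplots; survival observations are restricted to these.
CENTRAL_SUBPLOTS = frozenset({6, 7, 10, 11})


class ParseError(ValueError):
    """A table row could not be interpreted; the message names the line."""


class ValidationError(ValueError):
    """A record violates a structural invariant; the message names the record."""


# ---------------------------------------------------------------------------
# Measurement schedule


@dataclass(frozen=True)
class MeasurementSchedule:
    """Ordered measurement years and the survival intervals drawn from them.

    Each survival interval is a ``(start_year, end_year, period_index)``
    triple whose endpoints are consecutive schedule years. ``period_index``
    groups intervals into the three coefficient regimes: 1 = pre-earthquake,
    2 = 0-5 years post-earthquake, 3 = 5+ years post-earthquake.
    """

    years: tuple[int, ...]
    survival_intervals: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValidationError("schedule years must be strictly increasing")
        yrs = set(self.years)
        for start, end, period in self.survival_intervals:
            if start not in yrs or end not in yrs:
                raise ValidationError(
                    f"interval {start}-{end} endpoints must be schedule years"
                )
            if end <= start:
                raise ValidationError(f"interval {start}-{end} is not forward in time")
            if period not in (1, 2, 3):
                raise ValidationError(f"period index {period} not in {{1,2,3}}")

    @classmethod
    def default(cls) -> "MeasurementSchedule":
        """The eight-measurement 1974-2009 design with five survival intervals."""
        return cls(
            years=(1974, 1978, 1983, 1987, 1993, 1999, 2004, 2009),
            survival_intervals=(
                (1983, 1987, 1),
                (1987, 1993, 1),
                (1993, 1999, 2),
                (1999, 2004, 3),
                (2004, 2009, 3),
            ),
        )

    def delta_t(self, start_year: int, end_year: int) -> int:
        return end_year - start_year

    def previous_year(self, year: int) -> int | None:
        i = self.years.index(year)
        return self.years[i - 1] if i > 0 else None


# ---------------------------------------------------------------------------
# Standardization configuration


@dataclass(frozen=True)
class CovariateScale:
    """How one covariate maps from its measurement scale to the model scale."""

    zero_point: float
    transform: str = "identity"  # "identity" | "log"
    divisor: float = 1.0


@dataclass(frozen=True)
class StandardizationConfig:
    """Centring/transform constants for every standardized covariate.

    Defaults: basal area centred at 50 m2/ha; diameter at 164 mm;
    soil-available P on the natural-log scale centred at ln(14.88) = 2.7;
    landform index at 20 degrees; epicentre distance on the log scale centred
    at ln(18.17) = 2.9; elevation at 1000 m divided by 100 m. Growth
    covariates enter the model unstandardized (mm/yr).
    """

    scales: dict = field(
        default_factory=lambda: {
            "basal_area": CovariateScale(50.0),
            "diameter": CovariateScale(164.0),
            "soil_p": CovariateScale(2.7, transform="log"),
            "landform": CovariateScale(20.0),
            "distance": CovariateScale(2.9, transform="log"),
            "elevation": CovariateScale(1000.0, divisor=100.0),
        }
    )

    def scale_for(self, covariate: str) -> CovariateScale:
        try:
            return self.scales[covariate]
        except KeyError:
            raise KeyError(f"no standardization defined for covariate {covariate!r}")


# ---------------------------------------------------------------------------
# Records


@dataclass
class TreeRecord:
    """One tagged tree's measurement history.

    ``diameters`` maps measurement year to diameter (mm) and may contain
    gaps; ``status`` maps year to one of :data:`ALIVE`, :data:`DEAD`,
    :data:`NOT_TAGGED`. ``imputed_years`` records which diameters were
    produced by imputation rather than measurement.
    """

    tree_id: str
    plot_id: str
    subplot_index: int
    diameters: dict[int, float] = field(default_factory=dict)
    status: dict[int, str] = field(default_factory=dict)
    imputed_years: set[int] = field(default_factory=set)

    def validate(self) -> None:
        if not 1 <= self.subplot_index <= 16:
            raise ValidationError(
                f"tree {self.tree_id}: subplot {self.subplot_index} not in 1-16"
            )
        dead_seen = False
        for year in sorted(self.status):
            st = self.status[year]
            if st not in _STATUSES:
                raise ValidationError(f"tree {self.tree_id}: unknown status {st!r}")
            if dead_seen and st != DEAD:
                raise ValidationError(
                    f"tree {self.tree_id}: status {st!r} at {year} after death"
                )
            if st == DEAD:
                dead_seen = True
        first = self.first_tagging_year()
        if first is not None:
            d = self.diameters.get(first)
            if (
                d is not None
                and d < MIN_TAG_DIAMETER_MM
                and first not in self.imputed_years
            ):
                warnings.warn(
                    f"tree {self.tree_id}: first-tagging diameter {d:.1f} mm "
                    f"below the {MIN_TAG_DIAMETER_MM:.0f} mm tagging minimum",
                    stacklevel=2,
                )

    def first_tagging_year(self) -> int | None:
        tagged = [y for y, s in self.status.items() if s in (ALIVE, DEAD)]
        return min(tagged) if tagged else None

    def alive_at(self, year: int) -> bool:
        return self.status.get(year) == ALIVE

    def copy(self) -> "TreeRecord":
        return replace(
            self,
            diameters=dict(self.diameters),
            status=dict(self.status),
            imputed_years=set(self.imputed_years),
        )


@dataclass(frozen=True)
class PlotRecord:
    """Plot-level covariates shared by every tree of the plot."""

    plot_id: str
    transect_id: str
    elevation_m: float
    slope_deg: float
    landform_index: float
    soil_avP_ug_g: float
    epicentre_distance_km: float

    def validate(self, elevation_range: tuple[float, float] = (640.0, 1417.0)) -> None:
        lo, hi = elevation_range
        if not lo <= self.elevation_m <= hi:
            raise ValidationError(
                f"plot {self.plot_id}: elevation {self.elevation_m} m outside "
                f"[{lo}, {hi}] m"
            )
        if self.soil_avP_ug_g <= 0:
            raise ValidationError(f"plot {self.plot_id}: soil P must be positive")
        if self.epicentre_distance_km <= 0:
            raise ValidationError(f"plot {self.plot_id}: distance must be positive")


@dataclass(frozen=True)
class SurvivalObservation:
    """One tree x survival interval with its model-ready covariates."""

    tree_id: str
    plot_id: str
    start_year: int
    end_year: int
    delta_t_years: float
    period_index: int
    outcome: int
    diameter_std: float
    diameter_sq_std: float
    local_ba_std: float
    growth_prev: float
    growth_lag: float
    soil_p_std: float
    landform_std: float
    elevation_std: float
    distance_std: float


#: Column order of observations.csv; mirrors :class:`SurvivalObservation`.
OBS_COLUMNS = [
    "tree_id",
    "plot_id",
    "start_year",
    "end_year",
    "delta_t_years",
    "period_index",
    "outcome",
    "diameter_std",
    "diameter_sq_std",
    "local_ba_std",
    "growth_prev",
    "growth_lag",
    "soil_p_std",
    "landform_std",
    "elevation_std",
    "distance_std",
]

_TREE_COLUMNS = ["tree_id", "plot_id", "subplot", "year", "diameter_mm", "status"]
_PLOT_COLUMNS = [
    "plot_id",
    "transect_id",
    "elevation_m",
    "slope_deg",
    "landform_index",
    "soil_avP_ug_g",
    "epicentre_distance_km",
]


# ---------------------------------------------------------------------------
# Readers / writers


def read_tree_table(path, schedule: MeasurementSchedule | None = None) -> list[TreeRecord]:
    """Read a long-form tree table into validated :class:`TreeRecord` s.

    A row with an unparseable year/diameter/status raises :class:`ParseError`
    naming the offending line; a tree recorded alive after being recorded
    dead raises :class:`ValidationError` naming the tree. Diameter gaps are
    kept as missing values, never coerced to zero. An empty file yields an
    empty list.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if raw.empty:
        return []
    missing = [c for c in _TREE_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    trees: dict[str, TreeRecord] = {}
    for pos, row in enumerate(raw.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            year = int(row.year)
            subplot = int(row.subplot)
            status = str(row.status).strip()
            dia_raw = str(row.diameter_mm).strip()
            diameter = float(dia_raw) if dia_raw not in ("", "NA", "nan") else None
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row at line {line}: {exc}") from exc
        if status not in _STATUSES:
            raise ParseError(f"{path}: unknown status {status!r} at line {line}")
        key = str(row.tree_id)
        rec = trees.get(key)
        if rec is None:
            rec = TreeRecord(key, str(row.plot_id), subplot)
            trees[key] = rec
        rec.status[year] = status
        if diameter is not None:
            rec.diameters[year] = diameter
        if schedule is not None and year not in schedule.years:
            raise ParseError(f"{path}: year {year} at line {line} not in schedule")

    out = list(trees.values())
    for rec in out:
        rec.validate()
    return out


def write_tree_table(trees, path) -> None:
    rows = []
    for t in trees:
        for year in sorted(t.status):
            d = t.diameters.get(year)
            rows.append(
                {
                    "tree_id": t.tree_id,
                    "plot_id": t.plot_id,
                    "subplot": t.subplot_index,
                    "year": year,
                    "diameter_mm": "" if d is None else repr(float(d)),
                    "status": t.status[year],
                }
            )
    pd.DataFrame(rows, columns=_TREE_COLUMNS).to_csv(path, index=False)


def read_plot_table(path) -> list[PlotRecord]:
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if raw.empty:
        return []
    missing = [c for c in _PLOT_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    plots = []
    for row in raw.itertuples(index=False):
        rec = PlotRecord(
            plot_id=str(row.plot_id),
            transect_id=str(row.transect_id),
            elevation_m=float(row.elevation_m),
            slope_deg=float(row.slope_deg),
            landform_index=float(row.landform_index),
            soil_avP_ug_g=float(row.soil_avP_ug_g),
            epicentre_distance_km=float(row.epicentre_distance_km),
        )
        rec.validate()
        plots.append(rec)
    return plots


def write_plot_table(plots, path) -> None:
    rows = [
        {
            "plot_id": p.plot_id,
            "transect_id": p.transect_id,
            "elevation_m": repr(float(p.elevation_m)),
            "slope_deg": repr(float(p.slope_deg)),
            "landform_index": repr(float(p.landform_index)),
            "soil_avP_ug_g": repr(float(p.soil_avP_ug_g)),
            "epicentre_distance_km": repr(float(p.epicentre_distance_km)),
        }
        for p in plots
    ]
    pd.DataFrame(rows, columns=_PLOT_COLUMNS).to_csv(path, index=False)


def write_observations(observations: pd.DataFrame, path) -> None:
    """Write observations.csv; round-trips losslessly through :func:`read_observations`."""
    df = observations[OBS_COLUMNS].copy()
    df.to_csv(path, index=False, float_format="%.17g")


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["period_index"] = df["period_index"].astype(int)
    df["outcome"] = df["outcome"].astype(int)
    for col in OBS_COLUMNS[4:5] + OBS_COLUMNS[7:]:
        df[col] = df[col].astype(float)
    return df[OBS_COLUMNS]


def observations_frame(records) -> pd.DataFrame:
    """Build the canonical observations DataFrame from SurvivalObservation records."""
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])[
        OBS_COLUMNS
    ]


def basal_area_m2(diameter_mm: float) -> float:
    """Stem cross-sectional area (m^2) of a diameter in mm."""
    return math.pi * (diameter_mm / 2000.0) ** 2


def trees_to_frame(trees) -> pd.DataFrame:
    """Long-form DataFrame view of tree records (one row per tree x year)."""
    rows = []
    for t in trees:
        for year in sorted(t.status):
            rows.append(
                (t.tree_id, t.plot_id, t.subplot_index, year,
                 t.diameters.get(year, np.nan), t.status[year])
            )
    return pd.DataFrame(rows, columns=_TREE_COLUMNS)
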