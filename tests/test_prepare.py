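"""Growth windows, outlier rules, imputation, neighbourhood basal area,
standardization and observation assembly."""

import math
import random

import pandas as pd
import pytest
from hypothesis import given, strategies as st

import beechsurv as bs
from beechsurv.data_model import (
    ALIVE,
    DEAD,
    MeasurementSchedule,
    StandardizationConfig,
    TreeRecord,
)
from beechsurv.prepare import (
    CovariateStandardizer,
    ImputationError,
    PlotGrowthContext,
    clean_remeasurements,
    flag_growth_outliers,
    growth_windows,
    impute_diameter,
    interval_growth,
    local_basal_area,
    neighbourhood_subplots,
    standardize,
    unstandardize,
)

SCHED = MeasurementSchedule.default()


def make_tree(tree_id, diameters, subplot=6, plot_id="P1", dead_after=None):
    status = {}
    for y in SCHED.years:
        if y in diameters:
            status[y] = ALIVE
    if dead_after is not None:
        for y in SCHED.years:
            if y > dead_after:
                status[y] = DEAD
                diameters.pop(y, None)
    return TreeRecord(tree_id, plot_id, subplot, dict(diameters), status)


class TestIntervalGrowth:
    @pytest.mark.parametrize(
        "d0,d1,dt,expected",
        [(100, 110, 5, 2.0), (100, 100, 4, 0.0), (100, 95, 5, -1.0)],
    )
    def test_arithmetic(self, d0, d1, dt, expected):
        assert interval_growth(d0, d1, dt) == pytest.approx(expected)

    def test_missing_diameter_signals_imputation(self):
        with pytest.raises(ImputationError):
            interval_growth(float("nan"), 100.0, 5)
        with pytest.raises(ImputationError):
            interval_growth(None, 100.0, 5)


class TestOutlierRule:
    @pytest.mark.parametrize(
        "rate,flagged",
        [
            (10.0, False),
            (-3.0, False),
            (10.01, True),
            (-3.01, True),
            (12.3, True),
            (-3.5, True),
            (-2.9, False),
            (2.0, False),
        ],
    )
    def test_strict_boundaries(self, rate, flagged):
        out = flag_growth_outliers({"t1": [rate]})
        assert ("t1" in out) is flagged


class TestImputation:
    @staticmethod
    def _plot_mates(rate=1.5):
        # a plot of well-behaved trees all growing at `rate` mm/yr
        return [
            make_tree(
                f"ctx{i}",
                {y: d0 + rate * (y - 1974) for y in SCHED.years},
            )
            for i, d0 in enumerate([60, 90, 100, 110, 150, 200, 260, 320])
        ]

    def _context(self, rate=1.5):
        return PlotGrowthContext(self._plot_mates(rate), SCHED)

    def test_hand_arithmetic_oracle(self):
        """1983 anchor 100 mm + 4 years at the tercile median 1.5 mm/yr."""
        tree = make_tree("t1", {1974: 86.5, 1978: 92.5, 1983: 100.0, 1993: 115.0})
        ctx = self._context(rate=1.5)
        assert impute_diameter(tree, 1987, ctx) == pytest.approx(106.0)

    def test_transposed_digit_outlier_repaired(self):
        diam = {1974: 144.0, 1978: 150.0, 1983: 510.0, 1987: 163.5, 1993: 172.5}
        tree = make_tree("t1", diam)
        cleaned, log = clean_remeasurements([tree] + self._plot_mates(1.5), SCHED)
        assert len(cleaned) == 9
        fixed = next(t for t in cleaned if t.tree_id == "t1")
        assert 1983 in fixed.imputed_years
        predicted = 150.0 + 1.5 * 5  # anchor + median growth
        assert fixed.diameters[1983] == pytest.approx(predicted, abs=10.0)
        rates = [
            (fixed.diameters[b] - fixed.diameters[a]) / (b - a)
            for a, b in [(1978, 1983), (1983, 1987)]
        ]
        assert all(-3 < r < 10 for r in rates)

    def test_single_measurement_tree_excluded_and_logged(self):
        lone = TreeRecord("lone", "P1", 6, {1983: 100.0}, {1983: ALIVE, 1987: ALIVE})
        cleaned, log = clean_remeasurements([lone], SCHED)
        assert cleaned == []
        assert any(e.get("tree_id") == "lone" and e["action"] == "excluded" for e in log)


class TestLocalBasalArea:
    def test_empty_window_is_zero(self):
        assert local_basal_area([], 6, 1983) == 0.0

    def test_single_tree_arithmetic_oracle(self):
        tree = make_tree("t1", {1983: 164.0}, subplot=6)
        expected = math.pi * 0.082**2 / 0.0225
        assert local_basal_area([tree], 6, 1983) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.9389, abs=2e-4)

    def test_tree_outside_block_contributes_zero(self):
        inside = make_tree("a", {1983: 164.0}, subplot=6)
        outside = make_tree("b", {1983: 400.0}, subplot=16)  # not adjacent to 6
        assert 16 not in neighbourhood_subplots(6)
        assert local_basal_area([inside, outside], 6, 1983) == pytest.approx(
            local_basal_area([inside], 6, 1983)
        )

    def test_dead_tree_contributes_zero(self):
        t = make_tree("a", {1974: 164.0, 1978: 170.0}, subplot=6, dead_after=1978)
        assert local_basal_area([t], 6, 1983) == 0.0

    def test_central_blocks_lie_inside_plot(self):
        for sp in (6, 7, 10, 11):
            assert len(neighbourhood_subplots(sp)) == 9

    def test_additivity(self):
        rng = random.Random(5)
        trees = [
            make_tree(f"t{i}", {1983: rng.uniform(40, 400)}, subplot=rng.randint(1, 16))
            for i in range(40)
        ]
        whole = local_basal_area(trees, 7, 1983)
        part_a = local_basal_area(trees[:17], 7, 1983)
        part_b = local_basal_area(trees[17:], 7, 1983)
        assert whole == pytest.approx(part_a + part_b, rel=1e-12)


class TestStandardize:
    CFG = StandardizationConfig()

    @pytest.mark.parametrize(
        "covariate,raw",
        [
            ("soil_p", 14.88),
            ("elevation", 1000.0),
            ("diameter", 164.0),
            ("basal_area", 50.0),
            ("distance", 18.17),
            ("landform", 20.0),
        ],
    )
    def test_zero_points(self, covariate, raw):
        assert standardize(raw, self.CFG, covariate) == pytest.approx(0.0, abs=5e-4)

    def test_elevation_divisor(self):
        assert standardize(1100.0, self.CFG, "elevation") == pytest.approx(1.0)

    def test_log_domain_error(self):
        with pytest.raises(ValueError):
            standardize(-1.0, self.CFG, "soil_p")

    @given(
        st.sampled_from(
            ["soil_p", "elevation", "diameter", "basal_area", "distance", "landform"]
        ),
        st.floats(min_value=0.1, max_value=2000.0),
    )
    def test_round_trip_identity(self, covariate, value):
        z = standardize(value, self.CFG, covariate)
        assert unstandardize(z, self.CFG, covariate) == pytest.approx(value, rel=1e-9)

    def test_transformer_round_trip(self, small_dataset):
        df = pd.DataFrame(
            {
                "elevation_m": [p.elevation_m for p in small_dataset.plots],
                "landform_index": [p.landform_index for p in small_dataset.plots],
                "soil_avP_ug_g": [p.soil_avP_ug_g for p in small_dataset.plots],
                "epicentre_distance_km": [
                    p.epicentre_distance_km for p in small_dataset.plots
                ],
            }
        )
        tf = CovariateStandardizer().fit(df)
        z = tf.transform(df)
        assert z["elevation_m"].abs().max() < 5  # standardized scale
        back = tf.inverse_transform(z)
        pd.testing.assert_frame_equal(back, df, rtol=1e-9)

    def test_sklearn_params_contract(self):
        from sklearn.base import clone

        tf = CovariateStandardizer()
        assert "config" in tf.get_params()
        clone(tf)  # must be cloneable


class TestAssembleObservations:
    def test_default_intervals_and_periods(self, small_obs):
        got = sorted(
            small_obs[["start_year", "end_year", "period_index"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        assert got == [
            (1983, 1987, 1),
            (1987, 1993, 1),
            (1993, 1999, 2),
            (1999, 2004, 3),
            (2004, 2009, 3),
        ]

    def test_window_alignment_invariant(self):
        for start, _end, _p in SCHED.survival_intervals:
            (p0, p1), (l0, l1) = growth_windows(SCHED, start)
            assert p1 == start  # previous window ends at interval start
            assert l1 == p0  # lagged window ends where previous begins

    def test_late_recruit_needs_two_prior_windows(self, small_dataset):
        plot = small_dataset.plots[0]
        diam = {1987: 40.0, 1993: 45.0, 1999: 52.0, 2004: 60.0, 2009: 70.0}
        tree = make_tree("recruit", diam, subplot=6, plot_id=plot.plot_id)
        obs, _ = bs.assemble_observations([tree], [plot])
        assert obs.start_year.min() == 1999
        assert set(obs.start_year) == {1999, 2004}

    def test_edge_subplot_yields_no_observations(self, small_dataset):
        plot = small_dataset.plots[0]
        diam = {y: 100.0 + y - 1974 for y in SCHED.years}
        edge = make_tree("edge", dict(diam), subplot=1, plot_id=plot.plot_id)
        central = make_tree("mid", dict(diam), subplot=10, plot_id=plot.plot_id)
        obs, _ = bs.assemble_observations([edge, central], [plot])
        assert set(obs.tree_id) == {"mid"}

    def test_row_order_invariance(self, small_dataset):
        trees = list(small_dataset.trees)
        shuffled = list(trees)
        random.Random(3).shuffle(shuffled)
        a, _ = bs.assemble_observations(trees, small_dataset.plots)
        b, _ = bs.assemble_observations(shuffled, small_dataset.plots)
        pd.testing.assert_frame_equal(a, b)

    def test_unrecorded_at_end_excluded_not_dead(self, small_dataset):
        plot = small_dataset.plots[0]
        diam = {1974: 100.0, 1978: 104.0, 1983: 108.0}
        tree = TreeRecord(
            "vanish", plot.plot_id, 6, diam,
            {1974: ALIVE, 1978: ALIVE, 1983: ALIVE},
        )
        obs, log = bs.assemble_observations([tree], [plot])
        assert len(obs) == 0
        assert any(
            e.get("tree_id") == "vanish" and "unrecorded" in e["reason"] for e in log
        )

    def test_growth_columns_match_diameters(self, small_dataset, small_obs):
        trees = {t.tree_id: t for t in small_dataset.trees}
        sample = small_obs.sample(25, random_state=0)
        for row in sample.itertuples():
            t = trees[row.tree_id]
            (p0, p1), (l0, l1) = growth_windows(SCHED, row.start_year)
            assert row.growth_prev == pytest.approx(
                (t.diameters[p1] - t.diameters[p0]) / (p1 - p0)
            )
            assert row.growth_lag == pytest.approx(
                (t.diameters[l1] - t.diameters[l0]) / (l1 - l0)
            )
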