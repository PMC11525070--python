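"""Posterior summaries, basal-area series, curves export and the pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

import beechsurv as bs
from beechsurv.data_model import ALIVE, TreeRecord
from beechsurv.model import PosteriorFit
from beechsurv.report import (
    PipelineError,
    SUMMARY_REGISTRY,
    basal_area_series,
    export_survival_curves,
    run_pipeline,
    summarize_posterior,
)


def make_fit(draws: pd.DataFrame) -> PosteriorFit:
    return PosteriorFit(
        draws=draws,
        pointwise_loglik=np.full((len(draws), 3), -0.1, dtype=np.float32),
        chains=1,
        iterations=len(draws),
        burn_in=0,
        thin=1,
        seed=0,
        spec=bs.ModelSpec.selected(),
        plot_ids=[],
        rhat=pd.Series(dtype=float),
        ess=pd.Series(dtype=float),
        convergence_warnings=[],
    )


class TestSummarizePosterior:
    def test_degenerate_posterior_collapses(self):
        fit = make_fit(pd.DataFrame({"mu[1]": [2.0], "sigma_s": [0.5]}))
        table = summarize_posterior(fit)
        row = table[table.parameter == "muS_1"].iloc[0]
        assert row["mean"] == row["q2.5"] == row["q97.5"] == 2.0

    def test_normal_draws_match_closed_form(self):
        rng = np.random.default_rng(3)
        draws = pd.DataFrame({"mu[1]": rng.normal(1.0, 2.0, size=10001)})
        table = summarize_posterior(make_fit(draws))
        row = table[table.parameter == "muS_1"].iloc[0]
        assert row["mean"] == pytest.approx(1.0, abs=0.06)
        assert row["sd"] == pytest.approx(2.0, abs=0.06)
        assert row["q2.5"] == pytest.approx(1.0 - 1.96 * 2.0, abs=0.15)
        assert row["q97.5"] == pytest.approx(1.0 + 1.96 * 2.0, abs=0.15)

    def test_row_order_follows_registry(self, small_fit):
        table = summarize_posterior(small_fit.fit_)
        symbols = [s for _, s, _ in SUMMARY_REGISTRY]
        present = [p for p in table.parameter if p in symbols]
        assert present == [s for s in symbols if s in set(present)]
        assert table.parameter.iloc[-1] == "deviance"

    def test_percentiles_bracket_mean(self, small_fit):
        table = summarize_posterior(small_fit.fit_)
        ok = (table["q2.5"] <= table["mean"]) & (table["mean"] <= table["q97.5"])
        assert ok.mean() >= 0.95


class TestBasalAreaSeries:
    def _plot(self, pid="P1"):
        return bs.PlotRecord(pid, "T1", 1000.0, 20.0, 20.0, 14.88, 18.17)

    def test_single_tree_arithmetic(self):
        tree = TreeRecord("t1", "P1", 6, {1974: 200.0}, {1974: ALIVE})
        series = basal_area_series([tree], [self._plot()])
        row = series[series.year == 1974].iloc[0]
        assert row.mean_ba == pytest.approx(np.pi * 0.1**2 / 0.04, rel=1e-9)
        assert row.mean_ba == pytest.approx(0.7854, abs=2e-4)

    def test_all_dead_year_is_zero(self):
        tree = TreeRecord(
            "t1", "P1", 6, {1974: 200.0}, {1974: ALIVE, 1978: "dead"}
        )
        series = basal_area_series([tree], [self._plot()])
        assert series[series.year == 1978].mean_ba.iloc[0] == 0.0

    def test_identical_plots_have_zero_se(self):
        trees = [
            TreeRecord(f"t{i}", pid, 6, {1974: 150.0}, {1974: ALIVE})
            for i, pid in enumerate(["P1", "P2"])
        ]
        series = basal_area_series(trees, [self._plot("P1"), self._plot("P2")])
        assert series[series.year == 1974].se_ba.iloc[0] == pytest.approx(0.0)

    def test_se_definition(self, small_dataset):
        series = basal_area_series(small_dataset.trees, small_dataset.plots)
        assert (series.mean_ba > 0).all()
        assert series.n_plots.iloc[0] == len(small_dataset.plots)


class TestCurvesExport:
    def test_respects_central_trim(self, small_fit, small_obs):
        curves = export_survival_curves(small_fit.fit_, small_obs)
        for (period, elev), grp in curves.groupby(["period_index", "elevation_m"]):
            from beechsurv.model import central_growth_bounds

            lo, hi = central_growth_bounds(small_obs, period, elev)
            assert grp.growth_prev.min() >= lo - 1e-9
            assert grp.growth_prev.max() <= hi + 1e-9

    def test_default_elevations(self, small_fit, small_obs):
        curves = export_survival_curves(small_fit.fit_, small_obs)
        assert set(curves.elevation_m) == {800.0, 1000.0, 1200.0}


PIPELINE_CONFIG = {
    "data": {"synthetic": {"n_plots": 12, "n_transects": 6,
                           "stems_per_subplot": 2.5}},
    "mcmc": {"iterations": 300, "burn_in": 120, "thin": 3},
    "seed": 42,
}


@pytest.fixture(scope="module")
def pipeline_out(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    with np.errstate(all="ignore"):
        manifest = run_pipeline(dict(PIPELINE_CONFIG), out)
    return out, manifest


class TestPipeline:
    CONFIG = PIPELINE_CONFIG

    def test_manifest_study_shape(self, pipeline_out):
        _, manifest = pipeline_out
        assert manifest["n_survival_intervals"] == 5
        assert manifest["n_periods"] == 3
        assert manifest["seed"] == 42

    def test_artifacts_written(self, pipeline_out):
        out, _ = pipeline_out
        for name in ("trees.csv", "plots.csv", "observations.csv", "fit.nc",
                     "summary.csv", "curves.csv", "series.csv", "truth.json",
                     "manifest.json", "exclusions.csv"):
            assert (out / name).exists(), name

    def test_deterministic_manifests(self, pipeline_out, tmp_path):
        out, manifest = pipeline_out
        with np.errstate(all="ignore"):
            manifest2 = run_pipeline(dict(self.CONFIG), tmp_path / "again")
        drop = {"started", "finished"}
        a = {k: v for k, v in manifest.items() if k not in drop}
        b = {k: v for k, v in manifest2.items() if k not in drop}
        assert a == b
        s1 = pd.read_csv(out / "summary.csv")
        s2 = pd.read_csv(tmp_path / "again" / "summary.csv")
        pd.testing.assert_frame_equal(s1, s2)

    def test_resummarization_is_idempotent(self, pipeline_out):
        out, _ = pipeline_out
        fit = PosteriorFit.from_netcdf(out / "fit.nc")
        again = summarize_posterior(fit)
        stored = pd.read_csv(out / "summary.csv")
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), stored, rtol=1e-6, atol=1e-9
        )

    def test_missing_input_names_stage(self, tmp_path):
        cfg = {"data": {"trees": str(tmp_path / "none.csv"),
                        "plots": str(tmp_path / "none2.csv")}}
        with pytest.raises(PipelineError, match="load"):
            run_pipeline(cfg, tmp_path / "out")


class TestCLI:
    def test_simulate_prepare_round(self, tmp_path):
        from click.testing import CliRunner

        from beechsurv.cli import main

        runner = CliRunner()
        cfg = tmp_path / "sim.yaml"
        cfg.write_text("n_plots: 10\nn_transects: 5\nstems_per_subplot: 2.0\n")
        r = runner.invoke(
            main,
            ["simulate", "--config", str(cfg), "--seed", "3",
             "--out", str(tmp_path), "--no-measurement-error"],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        assert (tmp_path / "trees.csv").exists()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert "sigma_s" in truth and "gamma_g" in truth
        r2 = runner.invoke(
            main,
            ["prepare", "--trees", str(tmp_path / "trees.csv"),
             "--plots", str(tmp_path / "plots.csv"),
             "--out", str(tmp_path / "observations.csv")],
            catch_exceptions=False,
        )
        assert r2.exit_code == 0
        obs = pd.read_csv(tmp_path / "observations.csv")
        assert len(obs) > 0 and "growth_prev" in obs.columns
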