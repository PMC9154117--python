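"""Composed experiments: orderings, reproducibility, outputs, CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from foragesim import cli, experiments as ex

SMALL = {"n_runs": 40, "S": 100}


class TestFig1:
    @pytest.fixture(scope="class")
    def result(self):
        return ex.fig1(seed=11, config=SMALL)

    def test_perturbation_delays_convergence_by_over_5_decades(self, result):
        assert result["summary"]["perturbation"]["delay_log10"] > 5.0

    def test_variance_reduced_with_negative_feedback(self, result):
        stats = result["tables"]["ensemble_stats"]
        var = stats.pivot(index="patch", columns="variant", values="variance")
        assert (var["negative_feedback"] < var["positive_only"]).all()

    def test_ode_trajectories_cover_both_variants(self, result):
        ode = result["tables"]["ode_trajectories"]
        assert set(ode["variant"]) == {"positive_only", "negative_feedback"}
        # committed fractions end near the target in both variants
        final = ode[ode["time"] == ode["time"].max()]
        for _, grp in final.groupby("variant"):
            x = grp[grp["species"] != "U"].sort_values("species")["fraction"]
            assert abs(x.sum() - 1.0) < 0.05

    def test_boxplots_include_per_patch_and_pooled(self, result):
        box = result["tables"]["boxplots"]
        assert set(box["patch"]) == {"1", "2", "3", "pooled"}


class TestFig2:
    @pytest.fixture(scope="class")
    def result(self):
        return ex.fig2(seed=13, config={"n_runs": 40})

    def test_median_sse_higher_without_negative_feedback(self, result):
        tukey = result["summary"]["tukey"]
        assert tukey["positive_only"]["median"] > tukey["negative_feedback"]["median"]

    def test_sse_table_has_all_runs(self, result):
        tab = result["tables"]["sse"]
        assert len(tab) == 80
        assert (tab["sse"] >= 0).all()


class TestFig3:
    def test_monotonic_tradeoff_flags(self):
        result = ex.fig3(config={"z_grid": [0.5, 2.0, 8.0],
                                 "rho_grid": [100.0, 200.0, 400.0]})
        summary = result["summary"]
        assert summary["z_time_strictly_decreasing"]
        assert summary["z_error_strictly_increasing"]
        assert summary["rho_time_decreasing"]
        assert summary["rho_error_decreasing"]


class TestSweep:
    def test_variance_reduced_across_small_grid(self):
        result = ex.sweep(
            seed=5,
            config={"S_values": [60], "r_values": [50.0],
                    "quality_sets": [[0.75, 0.5, 0.25]], "n_runs": 40,
                    "t_end": 200.0, "eval_time": 200.0},
        )
        assert result["summary"]["fraction_ratio_below_1"] == 1.0

    def test_abandonment_sub_sweep_reports_orderings(self):
        result = ex.sweep(
            seed=5,
            config={"S_values": [60], "r_values": [50.0],
                    "quality_sets": [[0.75, 0.5, 0.25]], "n_runs": 30,
                    "t_end": 200.0, "eval_time": 200.0,
                    "a_values": [1e-4, 1e-3, 1e-2]},
        )
        tab = result["tables"]["sweep"]
        assert set(tab["a_positive_only"]) == {1e-4, 1e-3, 1e-2}
        assert not result["summary"]["positive_only_ever_below_negative"]


class TestAdaptation:
    def test_negative_feedback_reconverges_in_state_independent_time(self):
        result = ex.adaptation(seed=3, config={"n_inits": 6})
        cv = result["summary"]["cv"]
        assert cv["negative_feedback"] * 10.0 < cv["positive_only"]

    def test_reconvergence_from_new_fixed_point_is_instant(self):
        from foragesim import mean_field as mf
        from foragesim.parameterisation import build_system
        import foragesim as fs

        env = fs.make_environment([0.75, 0.5, 0.25])
        system = build_system("negative_feedback", env, a=1e-3, r=100.0, z=3.1)
        fp = mf.find_fixed_point(system).fixed_point
        assert mf.convergence_time(system, fp, fp.x, check_fixed_point=False) == 0.0


class TestAsocialBaseline:
    @pytest.fixture(scope="class")
    def result(self):
        return ex.asocial_baseline(seed=7, config={"n_runs": 20})

    def test_asocial_fixed_point_is_exactly_proportional(self, result):
        tab = result["tables"]["asocial_baseline"].set_index("variant")
        x = np.array(json.loads(tab.loc["asocial", "fixed_point"]))
        q = np.array([0.75, 0.5, 0.25])
        np.testing.assert_allclose(x / x.sum(), q / q.sum(), rtol=1e-10)

    def test_asocial_relaxation_is_at_least_100x_slower(self, result):
        summary = result["summary"]
        assert summary["asocial_vs_negative_eigen_timescale_ratio"] > 100.0
        ratios = summary["asocial_eigen_timescale_vs_social_convergence"]
        assert all(v > 100.0 for v in ratios.values())


class TestDeviationProbability:
    def test_positive_only_exceeds_negative_feedback_tail(self):
        result = ex.deviation_probability(seed=9, config={"n_runs": 60})
        p = result["summary"]["probabilities"]
        # delta is the negative-feedback 95th percentile by construction
        assert p["positive_only"] > 0.05
        assert p["negative_feedback"] <= 0.10

    @pytest.mark.parametrize("delta,expected", [(0.0, 1.0), (np.inf, 0.0)])
    def test_degenerate_thresholds(self, delta, expected):
        result = ex.deviation_probability(
            seed=9, config={"n_runs": 20, "delta": float(delta)})
        assert result["summary"]["probabilities"]["positive_only"] == expected


class TestOutputsAndCli:
    def test_manifest_checksums_are_reproducible(self, tmp_path):
        cfg = {"n_runs": 10, "S": 60, "t_end": 50.0, "eval_time": 50.0}
        m1 = json.loads(Path(ex.write_outputs(
            tmp_path / "a", "fig2", ex.fig2(seed=21, config=cfg))).read_text())
        m2 = json.loads(Path(ex.write_outputs(
            tmp_path / "b", "fig2", ex.fig2(seed=21, config=cfg))).read_text())
        assert m1["files"] == m2["files"]
        assert m1["config_hash"] == m2["config_hash"]

    def test_cli_experiment_writes_outputs(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"z_grid": [0.5, 2.0], "rho_grid": [200.0, 400.0]}))
        out = tmp_path / "out"
        res = runner.invoke(cli.main, ["experiment", "fig3", "--config", str(cfg),
                                       "--seed", "1", "--outdir", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "fig3_z_sweep.csv").exists()
        assert (out / "fig3_manifest.json").exists()

    def test_cli_simulate_ode_round_trip(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "model.yaml"
        cfg.write_text(yaml.safe_dump(
            {"variant": "negative_feedback", "qualities": [0.75, 0.5, 0.25],
             "a": 1e-3, "r": 100.0, "z": 3.1}))
        out = tmp_path / "traj.csv"
        res = runner.invoke(cli.main, ["simulate", "ode", "--config", str(cfg),
                                       "--t-end", "50", "--out", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd

        frame = pd.read_csv(out)
        assert set(frame.columns) == {"time", "species", "fraction"}
        assert out.with_suffix(".meta.json").exists()

    def test_cli_ssa_and_parameterise(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "model.yaml"
        cfg.write_text(yaml.safe_dump(
            {"variant": "negative_feedback", "qualities": [0.75, 0.5],
             "a": 1e-3, "r": 100.0, "z": 3.1}))
        res = runner.invoke(cli.main, ["simulate", "ssa", "--config", str(cfg),
                                       "-S", "50", "--runs", "2", "--t-end", "20",
                                       "--seed", "4"])
        assert res.exit_code == 0, res.output
        assert "patch_1" in res.output
        res2 = runner.invoke(cli.main, ["parameterise", "--config", str(cfg)])
        assert res2.exit_code == 0, res2.output
        blob = json.loads(res2.output)
        assert blob["z"] == pytest.approx(1e-3 * (100.0 / 0.625), rel=0.01)
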