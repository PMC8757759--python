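"""Model/results layer, report pipeline and CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hdsemg import (
    CoGMethodAgreement,
    ContractionAnalysis,
    SimulationConfig,
    SpeedComparison,
    run_pipeline,
    save_recording,
    simulate_recording,
)
from hdsemg.cli import main as cli_main

SMALL_COHORT = {
    "simulate": {
        "enabled": True,
        "n_subjects": 4,
        "speeds": [60, 90, 120],
        "duration_s": 2.5,
        "seed": 123,
    }
}


class TestContractionAnalysis:
    def test_fit_produces_complete_results(self, default_trial):
        rec, _ = default_trial
        res = ContractionAnalysis(rec).fit()
        assert res.features.mean_rms > 0
        assert 0 < res.features.entropy <= np.log2(59)
        assert len(res.maps) >= 2
        assert res.trajectory is not None
        row = res.to_row()
        for key in ("entropy", "cov", "cog_x", "cogx_mean", "cogx_range"):
            assert key in row
        text = res.summary()
        assert "entropy" in text and "CoG" in text

    def test_from_files_round_trip(self, tmp_path, default_trial):
        rec, _ = default_trial
        save_recording(rec, tmp_path / "s.tsv", tmp_path / "s.json")
        res = ContractionAnalysis.from_files(tmp_path / "s.tsv", tmp_path / "s.json").fit()
        direct = ContractionAnalysis(rec).fit()
        assert res.features.entropy == pytest.approx(direct.features.entropy, rel=1e-6)

    def test_differential_recording_rejected(self, default_trial):
        from hdsemg import to_single_differential

        rec, _ = default_trial
        with pytest.raises(ValueError, match="monopolar"):
            ContractionAnalysis(to_single_differential(rec))

    def test_plotting_smoke(self, default_trial):
        import matplotlib

        matplotlib.use("Agg")
        rec, _ = default_trial
        res = ContractionAnalysis(rec).fit()
        ax = res.plot_map()
        assert ax.get_ylabel().startswith("row")
        ax = res.plot_trajectory()
        assert ax.get_title() == "CoG trajectory"
        import matplotlib.pyplot as plt

        plt.close("all")


class TestSpeedComparison:
    def _table(self, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(12):
            base = rng.normal(5.5, 0.2)
            for k, speed in enumerate((60, 90, 120)):
                rows.append(
                    {
                        "subject": f"S{s}",
                        "speed": speed,
                        "entropy": base + k * effect + rng.normal(0, 0.05),
                        "cov": rng.normal(35, 5),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_cohort_finds_no_speed_effect(self):
        res = SpeedComparison(self._table(effect=0.0)).fit()
        assert not res.tests[res.tests["feature"] == "entropy"]["significant"].any()
        assert "no effect of speed" in res.summary() or res.any_significant

    def test_strong_effect_detected(self):
        res = SpeedComparison(self._table(effect=1.0)).fit()
        assert res.tests[res.tests["feature"] == "entropy"]["significant"].any()

    def test_normality_table_shape(self):
        res = SpeedComparison(self._table()).fit()
        assert set(res.normality["feature"]) == {"entropy", "cov"}
        assert len(res.normality) == 6  # 2 features x 3 speeds

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            SpeedComparison(pd.DataFrame({"speed": [60], "entropy": [5.0]}))


class TestCoGMethodAgreement:
    def test_from_table(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(5, 9, 12)
        y = rng.uniform(2.5, 3.5, 12)
        table = pd.DataFrame(
            {
                "cog_x": x,
                "cog_y": y,
                "cogx_mean": x + rng.normal(0, 0.05, 12),
                "cogy_mean": y + rng.normal(0, 0.05, 12),
                "speed": [60, 90, 120] * 4,
            }
        )
        res = CoGMethodAgreement(table=table).fit()
        pooled = res.correlations.query("speed == 'all'")
        assert (pooled["r2"] > 0.8).all()
        assert "Pearson" in res.summary()


class TestPipeline:
    def test_simulated_cohort_report(self, tmp_path):
        out = run_pipeline(SMALL_COHORT, tmp_path / "rep")
        feats = pd.read_csv(out / "features.tsv", sep="\t")
        assert len(feats) == 4 * 3  # subjects x speeds
        assert {"entropy", "cov", "intensity", "differential_intensity", "mean_rms", "median_frequency"} <= set(feats.columns)
        cog = pd.read_csv(out / "cog.tsv", sep="\t")
        assert {"cog_x", "cog_y", "cogx_mean", "cogy_range"} <= set(cog.columns)
        assert (out / "method_correlation.tsv").exists()
        assert (out / "speed_tests.tsv").exists()
        assert (out / "normality.tsv").exists()
        assert len(list((out / "maps").glob("*.tsv"))) == 12
        assert len(list((out / "trajectories").glob("*.tsv"))) == 12
        log = json.loads((out / "run_log.json").read_text())
        assert log["n_analysed"] == 12
        assert log["errors"] == []

    def test_rerun_is_byte_identical(self, tmp_path):
        a = run_pipeline(SMALL_COHORT, tmp_path / "a")
        b = run_pipeline(SMALL_COHORT, tmp_path / "b")
        for name in ("features.tsv", "cog.tsv", "method_correlation.tsv", "speed_tests.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_file_driven_trial(self, tmp_path):
        rec, _ = simulate_recording(SimulationConfig(seed=5, duration_s=2.5, speed_label=60))
        save_recording(rec, tmp_path / "s.tsv", tmp_path / "s.json")
        cfg = {
            "io": {
                "recordings": [
                    {"signal": str(tmp_path / "s.tsv"), "sidecar": str(tmp_path / "s.json")}
                ]
            }
        }
        out = run_pipeline(cfg, tmp_path / "rep")
        feats = pd.read_csv(out / "features.tsv", sep="\t")
        assert len(feats) == 1
        assert feats["speed"].iloc[0] == 60

    def test_empty_config_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no recordings"):
            run_pipeline({}, tmp_path / "rep")


class TestCLI:
    def test_simulate_then_features(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(
            cli_main, ["simulate", "--seed", "3", "--out", str(tmp_path / "trial")]
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "trial" / "ground_truth.json").exists()
        out = runner.invoke(
            cli_main,
            [
                "features",
                "--signal", str(tmp_path / "trial" / "signal.tsv"),
                "--sidecar", str(tmp_path / "trial" / "sidecar.json"),
                "--out", str(tmp_path / "row.tsv"),
            ],
        )
        assert out.exit_code == 0, out.output
        assert "entropy" in out.output
        assert (tmp_path / "row.tsv").exists()

    def test_cog_and_compare(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out", str(tmp_path / "t")])
        out = runner.invoke(
            cli_main,
            [
                "cog",
                "--signal", str(tmp_path / "t" / "signal.tsv"),
                "--sidecar", str(tmp_path / "t" / "sidecar.json"),
                "--out", str(tmp_path / "cogout"),
            ],
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "cogout" / "trajectory.tsv").exists()
        rng = np.random.default_rng(0)
        x = rng.uniform(5, 9, 9)
        pd.DataFrame(
            {"cog_x": x, "cog_y": x / 2, "cogx_mean": x + 0.01, "cogy_mean": x / 2 - 0.01}
        ).to_csv(tmp_path / "cog.tsv", sep="\t", index=False)
        out = runner.invoke(cli_main, ["compare", "--cog-table", str(tmp_path / "cog.tsv")])
        assert out.exit_code == 0, out.output
        assert "Pearson" in out.output

    def test_report_command(self, tmp_path):
        import yaml

        (tmp_path / "cfg.yaml").write_text(yaml.safe_dump(SMALL_COHORT))
        runner = CliRunner()
        out = runner.invoke(
            cli_main,
            ["report", "--config", str(tmp_path / "cfg.yaml"), "--out", str(tmp_path / "rep")],
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "rep" / "features.tsv").exists()
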