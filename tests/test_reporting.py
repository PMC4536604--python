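"""Tests for CSV I/O, study summaries, chart exports and the CLI."""

import dataclasses
import json

import numpy as np
import pytest
from click.testing import CliRunner

from cd4qc import cli, duplicate, reporting, synthetic
from cd4qc.reporting import SchemaError


@pytest.fixture
def study_config():
    """Three labs: two with both QC methods, one duplicate-only."""
    return synthetic.SimulationConfig(
        labs=(
            synthetic.LabProfile(lab_id="lab01", instrument="FACSCount",
                                 analytical_cv=0.035, uses_controls=True),
            synthetic.LabProfile(lab_id="lab02", instrument="FACSCalibur",
                                 analytical_cv=0.06, uses_controls=True),
            synthetic.LabProfile(lab_id="lab03", instrument="Cyflow",
                                 analytical_cv=0.02),
        ),
        n_days=120,
        seed=404,
        control_lots=(
            synthetic.ControlLotSpec(product="Multi-Check", level="normal",
                                     true_mean=650, shelf_life_days=30),
            synthetic.ControlLotSpec(product="IMMUNO-TROL", level="low",
                                     true_mean=280, shelf_life_days=120),
        ),
    )


class TestRoundTrips:
    def test_duplicate_pairs(self, tmp_path, study_config):
        pairs = synthetic.simulate_duplicate_stream(study_config)
        path = tmp_path / "pairs.csv"
        reporting.write_duplicate_pairs(pairs, path)
        result = reporting.read_duplicate_pairs(path)
        assert result.rejects.empty
        assert result.records == pairs

    def test_control_streams(self, tmp_path, study_config):
        lots, runs = synthetic.simulate_control_stream(study_config)
        reporting.write_control_lots(lots, tmp_path / "lots.csv")
        reporting.write_control_runs(runs, tmp_path / "runs.csv")
        assert reporting.read_control_lots(tmp_path / "lots.csv").require_clean() == lots
        assert reporting.read_control_runs(tmp_path / "runs.csv").require_clean() == runs

    def test_unit_conversion(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "lab_id,instrument,date,level,day1_count,day2_count\n"
            "L1,FACSCount,2013-01-01,normal,0.6,0.63\n"
        )
        records = reporting.read_duplicate_pairs(
            tmp_path / "p.csv", unit="cells/mL"
        ).require_clean()
        assert records[0].day1_count == pytest.approx(600.0)
        with pytest.raises(SchemaError):
            reporting.read_duplicate_pairs(tmp_path / "p.csv", unit="furlongs")


class TestValidation:
    def test_empty_file_with_header(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "lab_id,instrument,date,level,day1_count,day2_count\n"
        )
        result = reporting.read_duplicate_pairs(tmp_path / "p.csv")
        assert result.records == [] and result.rejects.empty

    def test_bad_row_soft_rejected_with_line_number(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "lab_id,instrument,date,level,day1_count,day2_count\n"
            "L1,FACSCount,2013-01-01,normal,500,510\n"
            "L1,FACSCount,2013-01-02,normal,abc,510\n"
        )
        result = reporting.read_duplicate_pairs(tmp_path / "p.csv")
        assert len(result.records) == 1
        assert len(result.rejects) == 1
        assert result.rejects.iloc[0]["line"] == 3
        assert "abc" in result.rejects.iloc[0]["reason"]
        with pytest.raises(SchemaError):
            result.require_clean()

    def test_missing_column_hard_error(self, tmp_path):
        (tmp_path / "p.csv").write_text("lab_id,date\nL1,2013-01-01\n")
        with pytest.raises(SchemaError, match="missing required columns"):
            reporting.read_duplicate_pairs(tmp_path / "p.csv")


class TestStudySummary:
    def build(self, config):
        pairs = synthetic.simulate_duplicate_stream(config)
        by_lab = {}
        for p in pairs:
            by_lab.setdefault(p.lab_id, []).append(p)
        summaries = {
            lab: duplicate.long_term_precision(ps) for lab, ps in by_lab.items()
        }
        instruments = {lab: ps[0].instrument for lab, ps in by_lab.items()}
        return pairs, summaries, instruments

    def test_duplicate_only_lab_gets_sentinel_cells(self, study_config):
        from cd4qc import controls

        pairs, summaries, instruments = self.build(study_config)
        lots, runs = synthetic.simulate_control_stream(study_config)
        control_cv = {}
        for lab_id in ("lab01", "lab02"):
            control_cv[lab_id] = controls.monthly_cv_series(
                [r for r in runs if r.lab_id == lab_id]
            )
        summary = reporting.summarize_study(
            summaries, instruments=instruments, control_cv=control_cv,
            control_products={"lab01": "Multi-Check/IMMUNO-TROL",
                              "lab02": "Multi-Check/IMMUNO-TROL"},
        )
        frame = summary.formatted.set_index("lab_id")
        assert frame.loc["lab03", "control_mean_cv"] == reporting.SENTINEL
        assert frame.loc["lab01", "control_mean_cv"] != reporting.SENTINEL
        assert "Multi-Check" in frame.loc["lab01", "control_mean_cv"]
        machine = summary.machine.set_index("lab_id")
        assert np.isnan(machine.loc["lab03", "control_mean_cv"])

    def test_noise_free_study_summary(self, noise_free_config):
        pairs, summaries, instruments = self.build(noise_free_config)
        summary = reporting.summarize_study(summaries, instruments=instruments)
        row = summary.machine.iloc[0]
        assert row["duplicate_mean_abs_pv"] == pytest.approx(0.0)
        assert row["r_squared"] == pytest.approx(1.0)
        assert row["n_duplicate_failures"] == 0

    def test_formatted_matches_machine_to_rounding(self, study_config):
        """The printed cells are the machine statistics, only rounded."""
        _, summaries, instruments = self.build(study_config)
        summary = reporting.summarize_study(summaries, instruments=instruments)
        for _, formatted_row in summary.formatted.iterrows():
            machine_row = summary.machine.set_index("lab_id").loc[
                formatted_row["lab_id"]
            ]
            lead = formatted_row["duplicate_mean_pv"].split(",")[0]
            assert float(lead) == pytest.approx(
                machine_row["duplicate_mean_abs_pv"], abs=0.05
            )


class TestChartExports:
    def test_bland_altman_reference_lines(self, study_config):
        from cd4qc import qc_stats

        pairs = [p for p in synthetic.simulate_duplicate_stream(study_config)
                 if p.lab_id == "lab01"]
        verdicts = duplicate.evaluate_pairs(pairs)
        frame = reporting.export_chart_data("bland_altman", verdicts=verdicts)
        normal = frame[frame["level"] == "normal"]
        ba = qc_stats.bland_altman(
            [p.day1_count for p in pairs if p.level == "normal"],
            [p.day2_count for p in pairs if p.level == "normal"],
        )
        assert normal["bias"].iloc[0] == pytest.approx(ba.bias)
        assert normal["loa_lower"].iloc[0] == pytest.approx(ba.loa_lower)
        assert normal["loa_upper"].iloc[0] == pytest.approx(ba.loa_upper)

    def test_lj_export_has_sd_band_columns(self, study_config):
        from cd4qc import controls

        lots, runs = synthetic.simulate_control_stream(study_config)
        lot = next(l for l in lots if l.product == "IMMUNO-TROL")
        lot_runs = [r for r in runs if r.lot_id == lot.lot_id and r.lab_id == "lab01"]
        updated, evals = controls.analyze_lot_history(lot_runs, lot)
        frame = reporting.export_chart_data("lj", evaluations=evals, lot=updated)
        for col in ("mean", "sd_minus_2", "sd_plus_2", "sd_minus_3", "sd_plus_3"):
            assert col in frame.columns
        assert frame["sd_plus_2"].iloc[0] == pytest.approx(
            updated.lab_mean + 2 * updated.lab_sd
        )

    def test_pv_trend_export_has_threshold_lines(self, study_config):
        pairs = [p for p in synthetic.simulate_duplicate_stream(study_config)
                 if p.lab_id == "lab01"]
        frame = reporting.export_chart_data(
            "pv_trend", verdicts=duplicate.evaluate_pairs(pairs)
        )
        assert (frame["ref_upper"] == 20).all() and (frame["ref_lower"] == -20).all()

    def test_regression_export_r2_consistent(self, study_config):
        pairs = [p for p in synthetic.simulate_duplicate_stream(study_config)
                 if p.lab_id == "lab01"]
        frame = reporting.export_chart_data(
            "regression", verdicts=duplicate.evaluate_pairs(pairs)
        )
        assert set(frame["level"]) == {"low", "normal"}
        assert ((frame["r_squared"] > 0) & (frame["r_squared"] <= 1)).all()

    def test_unknown_kind(self):
        with pytest.raises(Exception, match="unknown chart kind"):
            reporting.export_chart_data("pie")


class TestCLI:
    def run_pipeline(self, tmp_path, config, seed=None):
        runner = CliRunner()
        tmp_path.mkdir(parents=True, exist_ok=True)
        (tmp_path / "config.yaml").write_text(synthetic.config_to_yaml(config))
        sim_dir = tmp_path / "sim"
        args = ["simulate", "--config", str(tmp_path / "config.yaml"),
                "--out-dir", str(sim_dir)]
        if seed is not None:
            args += ["--seed", str(seed)]
        result = runner.invoke(cli.main, args, catch_exceptions=False)
        assert result.exit_code == 0, result.output
        for cmd, extra in (
            ("analyze-duplicate", ["--pairs", str(sim_dir / "duplicate_pairs.csv")]),
            ("analyze-control", ["--lots", str(sim_dir / "control_lots.csv"),
                                 "--runs", str(sim_dir / "control_runs.csv")]),
            ("summarize", ["--pairs", str(sim_dir / "duplicate_pairs.csv"),
                           "--lots", str(sim_dir / "control_lots.csv"),
                           "--runs", str(sim_dir / "control_runs.csv")]),
        ):
            out_dir = tmp_path / cmd
            result = runner.invoke(
                cli.main, [cmd, *extra, "--out-dir", str(out_dir)],
                catch_exceptions=False,
            )
            assert result.exit_code == 0, result.output
        return tmp_path

    def test_end_to_end(self, tmp_path, study_config):
        root = self.run_pipeline(tmp_path, study_config)
        summary = (root / "summarize" / "study_summary.csv").read_text()
        assert "lab01" in summary and "lab03" in summary
        rates = json.loads((root / "summarize" / "failure_rates.json").read_text())
        assert "duplicate_per_lab_year" in rates
        assert any(k.startswith("Multi-Check") for k in rates)
        verdicts = (root / "analyze-duplicate" / "verdicts.csv").read_text()
        assert verdicts.splitlines()[0].endswith("pv,status,reason")
        evals = (root / "analyze-control" / "evaluations.csv").read_text()
        assert "active_range" in evals.splitlines()[0]

    def test_byte_identical_reruns(self, tmp_path, study_config):
        root_a = self.run_pipeline(tmp_path / "a", study_config)
        root_b = self.run_pipeline(tmp_path / "b", study_config)
        for rel in ("sim/duplicate_pairs.csv", "summarize/study_summary.csv",
                    "summarize/study_summary_full.csv",
                    "analyze-control/evaluations.csv"):
            assert (root_a / rel).read_bytes() == (root_b / rel).read_bytes()

    def test_seed_override_changes_stream(self, tmp_path, study_config):
        root_a = self.run_pipeline(tmp_path / "a", study_config)
        root_b = self.run_pipeline(tmp_path / "b", study_config, seed=999)
        assert (root_a / "sim/duplicate_pairs.csv").read_bytes() != (
            root_b / "sim/duplicate_pairs.csv"
        ).read_bytes()

    def test_export_chart_command(self, tmp_path, study_config):
        root = self.run_pipeline(tmp_path, study_config)
        runner = CliRunner()
        out = tmp_path / "chart.csv"
        result = runner.invoke(
            cli.main,
            ["export-chart", "--kind", "bland_altman",
             "--pairs", str(root / "sim" / "duplicate_pairs.csv"),
             "--lab", "lab01", "--out", str(out)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0, result.output
        header = out.read_text().splitlines()[0]
        assert "bias" in header and "loa_lower" in header
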