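"""Synthetic-data generation, run configuration and pipeline plumbing."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from rfadope.cli import main as cli_main
from rfadope.config import RunConfig
from rfadope.pipeline import run, summary_row
from rfadope.synthetic import (
    SweepGrid,
    exvivo_reference_table,
    make_sweep_configs,
    manufactured_cases,
    simulate_phantom_measurements,
    write_fixtures,
)


class TestPhantomMeasurements:
    def test_reproducible_under_seed(self):
        s1, d1 = simulate_phantom_measurements(n=10, seed=42)
        s2, d2 = simulate_phantom_measurements(n=10, seed=42)
        pd.testing.assert_frame_equal(d1, d2)

    def test_different_seeds_differ_but_summarize_alike(self):
        _, d1 = simulate_phantom_measurements(n=10, seed=1)
        _, d2 = simulate_phantom_measurements(n=10, seed=2)
        assert not d1.z_ohm.equals(d2.z_ohm)
        m1 = d1[d1.group == "agar"].z_ohm.mean()
        m2 = d2[d2.group == "agar"].z_ohm.mean()
        assert abs(m1 - 322.4) < 3 * 2.7 / np.sqrt(10)
        assert abs(m2 - 322.4) < 3 * 2.7 / np.sqrt(10)

    def test_zero_sd_gives_exact_mean(self):
        groups = {"g": {"mean": 100.0, "sd": 0.0}}
        _, df = simulate_phantom_measurements(groups, n=5, seed=0)
        assert np.allclose(df.z_ohm, 100.0)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            simulate_phantom_measurements(n=1)


class TestSweepGrid:
    def test_default_grid_size(self):
        grid = SweepGrid()
        assert grid.size == 81
        assert len(make_sweep_configs(grid)) == 81

    def test_nd_only_grid_deduplicates_to_voltages(self):
        grid = SweepGrid(dopants=(("none", 0),))
        assert len(make_sweep_configs(grid, deduplicate_nd=True)) == 3

    def test_configs_validate_and_round_trip(self, tmp_path):
        for rec in make_sweep_configs(SweepGrid())[:6]:
            cfg = RunConfig(
                dopant=rec["dopant"],
                concentration_pct=rec["concentration_pct"],
                doped_zone_cm=rec["doped_zone_cm"],
                v_applied=rec["v_applied"],
            )
            path = tmp_path / "cfg.yaml"
            cfg.to_file(path)
            assert RunConfig.from_file(path) == cfg


class TestManufacturedCases:
    def test_closed_form_answers_attached(self):
        cases = manufactured_cases()
        assert cases["concentric_shell"]["impedance_ohm"] == pytest.approx(71.62, abs=0.01)
        assert cases["uniform_heating"]["slope_c_per_s"] == pytest.approx(0.01)
        assert cases["constant_t_damage"]["omega"] == pytest.approx(4.6, abs=0.01)


class TestExvivoFixture:
    def test_rows(self):
        df = exvivo_reference_table()
        assert len(df) == 3
        aunp = df[df.group == "AuNPs"].iloc[0]
        assert (aunp.transverse_cm, aunp.axial_cm, aunp.t_rolloff_s) == (3.7, 4.1, 432.0)
        nd = df[df.group == "ND"].iloc[0]
        assert (nd.transverse_cm, nd.axial_cm, nd.t_rolloff_s) == (2.4, 3.4, 281.0)

    def test_fixture_tree_regenerates_identically(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_fixtures(a, seed=7, n=4)
        write_fixtures(b, seed=7, n=4)
        for name in ("phantom_samples.csv", "sweep_configs.yaml"):
            assert (a / name).read_bytes() == (b / name).read_bytes()


class TestRunConfig:
    def test_defaults_match_study_conditions(self):
        cfg = RunConfig()
        assert cfg.rolloff_threshold == 100.0
        assert cfg.coolant_temperature == 8.0
        assert cfg.initial_temperature == 37.0
        assert cfg.sigma_temp_coeff == 0.015

    def test_unsupported_zone_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(doped_zone_cm=5.0)

    def test_doped_run_needs_zone_and_concentration(self):
        with pytest.raises(ValueError):
            RunConfig(dopant="nacl", concentration_pct=5.0, doped_zone_cm=0.0)
        with pytest.raises(ValueError):
            RunConfig(dopant="nacl", concentration_pct=0.0, doped_zone_cm=2.0)

    def test_hash_stable_and_discriminating(self):
        a = RunConfig(v_applied=50.0)
        b = RunConfig(v_applied=70.0)
        assert a.config_hash() == RunConfig(v_applied=50.0).config_hash()
        assert a.config_hash() != b.config_hash()


class TestPipeline:
    def test_run_is_deterministic_and_writes_outputs(self, tmp_path):
        cfg = RunConfig(
            v_applied=0.0,
            max_duration=1.0,
            time_step=0.5,
            refinement=1,
            out_dir=str(tmp_path / "out"),
        )
        r1 = run(cfg)
        row1 = summary_row(cfg, r1)
        r2 = run(cfg)
        row2 = summary_row(cfg, r2)
        assert row1 == row2
        out = tmp_path / "out"
        assert (out / "trace.csv").exists()
        assert (out / "summary.csv").exists()
        assert (out / "fields.vtk").exists()
        assert (out / "config.yaml").exists()


class TestReproduceTables:
    def test_restricted_grid_emits_comparison_tables(self, tmp_path):
        """A reduced sweep produces published-structure tables with
        deviation columns against the reference values."""
        from rfadope.pipeline import reproduce_tables

        grid = SweepGrid(
            dopants=(("none", 0), ("aunp", 10)),
            zone_diameters_cm=(2.0,),
            voltages=(90.0,),
        )
        tables = reproduce_tables(tmp_path, grid, refinement=1, time_step=0.5)
        df = tables[2.0]
        assert len(df) == 2
        assert "z_i_ohm" in df.columns and "t100_90v_s" in df.columns
        assert "dev_z_i_ohm_pct" in df.columns and "flag_z_i_ohm" in df.columns
        assert (tmp_path / "table_zone_2cm.csv").exists()
        assert (tmp_path / "sweep_summary.csv").exists()


class TestCli:
    def test_estimate_sigma_cli(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["estimate-sigma", "--z", "240.4", "--refinement", "1"]
        )
        assert result.exit_code == 0
        assert "sigma_s_per_m" in result.output

    def test_verify_cli(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["verify"])
        assert result.exit_code == 0
        assert "concentric_shell" in result.output
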