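"""Pipeline-level behaviour: determinism, baselines, degenerate limits, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from nanodef import cli
from nanodef import pipelines as P
from nanodef import sources as S


class TestDeterminism:
    def test_same_config_same_result(self, two_step_run):
        a = two_step_run("solid-gold", 50.0)
        cfg = P.SimulationConfig(pipeline="two-step", np_model="solid-gold",
                                 energy_kev=50.0, histories=6000, seed=101)
        b = P.run_two_step(cfg, keep_phase_space=False)
        assert a.def_results["integrated"].value == b.def_results["integrated"].value

    def test_phase_space_file_bytes_reproducible(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            cfg = P.SimulationConfig(pipeline="two-step", np_model="core-shell",
                                     energy_kev=50.0, histories=1500, seed=77)
            res = P.run_two_step(cfg)
            path = tmp_path / f"{tag}.phsp"
            S.write_phase_space(path, res.tallies["phase_space"]["core-shell"])
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_config_hash_stability(self):
        cfg = P.SimulationConfig(pipeline="cell")
        assert P.config_hash(cfg.as_dict()) == P.config_hash(cfg.as_dict())


class TestCellPipeline:
    def test_zero_concentration_def_exactly_one(self):
        cfg = P.SimulationConfig(pipeline="cell", concentration_mg_ml=0.0,
                                 histories=500, seed=4, placement_seeds=1)
        res = P.run_cell(cfg)
        assert res.def_results["cytoplasm"].value == 1.0
        assert res.def_results["nucleus"].value == 1.0

    def test_concentration_resolves_via_count_table(self, cell_run):
        res = cell_run("core-shell", 50.0, 50.0)
        assert res.diagnostics["np_count"] == 3074

    def test_def_exceeds_unity_with_gold(self, cell_run):
        res = cell_run("solid-gold", 50.0, 50.0)
        r = res.def_results["cytoplasm"]
        assert r.value - 2 * r.stderr > 1.5


class TestBrachyPipeline:
    def test_targeted_concentration_resolution(self):
        assert P.resolve_targeted_concentration(50.0) == pytest.approx(74.0)
        assert P.resolve_targeted_concentration(10.0, 1.5) == pytest.approx(15.0)

    def test_delta_spectrum_degenerates_to_monoenergetic(self, cell_run):
        """A single-bin spectrum source reproduces the monoenergetic run."""
        mono = cell_run("solid-gold", 50.0, 50.0)
        cfg = P.SimulationConfig(pipeline="cell", np_model="solid-gold",
                                 concentration_mg_ml=50.0,
                                 spectrum=S.delta_spectrum(50.0),
                                 histories=25000, seed=303, placement_seeds=1)
        spec_run = P.run_cell(cfg)
        a = mono.def_results["cytoplasm"]
        b = spec_run.def_results["cytoplasm"]
        assert abs(a.value - b.value) <= 2.5 * np.hypot(a.stderr, b.stderr)

    def test_brachy_arm_table(self):
        cfg = P.SimulationConfig(pipeline="brachy", histories=4000, seed=5,
                                 placement_seeds=1)
        res = P.run_brachy(cfg, spectrum=S.make_ir192_like_spectrum(resolution_kev=5.0))
        assert res.diagnostics["targeted_concentration_mg_ml"] == pytest.approx(74.0)
        for arm in ("core-shell", "solid-gold", "targeted-core-shell"):
            assert f"{arm}/cytoplasm" in res.def_results
            assert f"{arm}/nucleus" in res.def_results


class TestBfieldScan:
    def test_gyroradius_diagnostics_and_equivalence_report(self):
        cfg = P.SimulationConfig(pipeline="bscan", np_model="solid-gold",
                                 energy_kev=50.0, histories=2500, seed=8)
        res = P.run_bfield_scan(cfg, b_list=(0.0, 1.0), mode="single-np")
        assert res.diagnostics["gyroradius_mm"][1.0] == pytest.approx(0.772, abs=0.002)
        assert 1.0 in res.diagnostics["equivalence_vs_B0"]
        # doubled beam diameter for the field study
        assert res.config["beam_diameter_nm"] is None  # original config untouched


class TestEnergyScan:
    def test_requires_two_energies(self):
        cfg = P.SimulationConfig(pipeline="escan", histories=100, seed=1)
        with pytest.raises(ValueError):
            P.run_energy_scan(cfg, energies=(50.0,))

    def test_scan_reports_peak_and_values(self, two_step_run):
        # reuse cached arms through the same cached runner seeds
        cfg = P.SimulationConfig(pipeline="escan", np_model="solid-gold",
                                 histories=2500, seed=13)
        res = P.run_energy_scan(cfg, energies=(50.0, 150.0), mode="two-step")
        assert set(res.diagnostics["def_by_energy"]) == {"50", "150"}
        assert res.diagnostics["peak_energy_kev"] in (50.0, 150.0)


class TestCli:
    def test_cell_subcommand_writes_summary(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "run"
        result = runner.invoke(cli.main, [
            "cell", "--histories", "400", "--energy", "50", "--np-model", "solid-gold",
            "--concentration", "5", "--seed", "3", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        summary = json.loads((out / "summary.json").read_text())
        assert "cytoplasm" in summary["def"]
        assert summary["seed"] == 3

    def test_two_step_subcommand(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ts"
        result = runner.invoke(cli.main, [
            "two-step", "--histories", "800", "--energy", "50",
            "--np-model", "core-shell", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert (out / "profile_core-shell.csv").exists()
        assert (out / "summary.json").exists()
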