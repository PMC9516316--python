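"""Spectrum generation, energy sampling, phase-space I/O and toy fixtures."""

import numpy as np
import pytest
from scipy import stats

from nanodef import engine
from nanodef import sources as S


class TestIr192Spectrum:
    def test_normalisation(self):
        spec = S.make_ir192_like_spectrum(resolution_kev=1.0, scatter_fraction=0.3)
        assert spec.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(spec.weights >= 0)

    def test_zero_scatter_supports_only_lines(self):
        spec = S.make_ir192_like_spectrum(resolution_kev=1.0, scatter_fraction=0.0)
        occupied = np.nonzero(spec.weights)[0]
        line_bins = set()
        for e_line, _ in S.IR192_LINES:
            line_bins.add(int((e_line - spec.edges_kev[0]) / 1.0))
        assert set(occupied) == line_bins
        # weights proportional to published intensities
        total = sum(i for _, i in S.IR192_LINES)
        for e_line, intensity in S.IR192_LINES:
            idx = int((e_line - spec.edges_kev[0]) / 1.0)
            assert spec.weights[idx] == pytest.approx(intensity / total, rel=1e-9)

    @pytest.mark.parametrize("scatter", [0.2, 0.35, 0.5])
    def test_mean_energy_in_brachytherapy_range(self, scatter):
        spec = S.make_ir192_like_spectrum(scatter_fraction=scatter)
        assert 250.0 <= spec.mean_energy_kev <= 400.0

    def test_invalid_resolution_raises(self):
        with pytest.raises(S.SpectrumError):
            S.make_ir192_like_spectrum(resolution_kev=0.0)

    def test_csv_round_trip(self, tmp_path):
        spec = S.make_ir192_like_spectrum(resolution_kev=5.0)
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        back = S.EnergySpectrum.from_csv(path)
        assert np.allclose(back.edges_kev, spec.edges_kev)
        assert np.allclose(back.weights, spec.weights)


class TestSampleEnergy:
    def test_single_bin_interior(self, rng):
        spec = S.delta_spectrum(100.0, width_kev=2.0)
        for _ in range(100):
            e = S.sample_energy(spec, rng)
            assert 99.0 <= e <= 101.0

    def test_bin_frequencies_chi2(self, rng):
        spec = S.EnergySpectrum(np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
                                np.array([0.1, 0.4, 0.3, 0.2]))
        n = 100_000
        samples = S.sample_energies(spec, n, rng)
        counts, _ = np.histogram(samples, bins=spec.edges_kev)
        p = stats.chisquare(counts, n * spec.weights).pvalue
        assert p > 0.01

    def test_seeded_reproducibility(self):
        spec = S.make_ir192_like_spectrum()
        a = S.sample_energies(spec, 100, np.random.default_rng(5))
        b = S.sample_energies(spec, 100, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestPhaseSpaceIO:
    def test_round_trip_lossless(self, tmp_path, rng):
        phsp = S.make_toy_phase_space(50, energy_kev=lambda r: 1.0 + 30.0 * r.random(), seed=4)
        path = tmp_path / "records.phsp"
        S.write_phase_space(path, phsp)
        back = S.read_phase_space(path)
        assert np.array_equal(back.position_nm, phsp.position_nm)
        assert np.array_equal(back.direction, phsp.direction)
        assert np.array_equal(back.energy_kev, phsp.energy_kev)
        assert np.array_equal(back.weight, phsp.weight)
        assert back.header["np_model"] == "toy"

    def test_empty_phase_space_file(self, tmp_path):
        phsp = S.make_toy_phase_space(0)
        path = tmp_path / "empty.phsp"
        S.write_phase_space(path, phsp)
        back = S.read_phase_space(path)
        assert len(back) == 0

    def test_truncated_line_names_line_number(self, tmp_path):
        phsp = S.make_toy_phase_space(3, seed=1)
        path = tmp_path / "broken.phsp"
        S.write_phase_space(path, phsp)
        lines = path.read_text().splitlines()
        lines[-1] = " ".join(lines[-1].split()[:4])  # drop fields
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(S.PhaseSpaceParseError, match=r"line \d+"):
            S.read_phase_space(path)


class TestToyPhaseSpace:
    def test_zero_records(self):
        assert len(S.make_toy_phase_space(0)) == 0

    def test_all_records_outward(self):
        phsp = S.make_toy_phase_space(500, seed=9)
        dots = (phsp.position_nm * phsp.direction).sum(axis=1)
        assert np.all(dots >= 0)

    def test_monoenergetic_dose_ends_at_csda_range(self):
        """21.4 keV electrons (straight tracks) stop just inside 9.95 um."""
        phsp = S.make_toy_phase_space(300, energy_kev=21.4, seed=2)
        res = engine.run_step2(phsp, seed=3, scatter=False)
        dose, _ = res.profile.dose_gy_per_source()
        edges = res.profile.grid.edges_nm
        nonzero_hi = edges[1:][dose > 0].max()
        assert 9_000.0 <= nonzero_hi <= 9_950.0
        beyond = dose[edges[:-1] >= 9_800.0]
        assert np.all(beyond == 0)

    def test_step2_matches_analytic_csda_kernel(self):
        """Shell doses from the point-source CSDA flux model within 10%.

        Oracle: N electrons of energy E0 leave the surface isotropically
        outward without angular diffusion; at path length d the local dose is
        S(E(d)) / (4 pi r^2 rho) per electron.
        """
        from nanodef.physics import collision_stopping_power, water_stopping_model
        from nanodef.materials import WATER

        e0 = 30.0
        phsp = S.make_toy_phase_space(4000, energy_kev=e0, seed=6)
        res = engine.run_step2(phsp, seed=7, scatter=False)
        dose, _ = res.profile.dose_gy_per_source()
        grid = res.profile.grid
        model = water_stopping_model()
        r0 = grid.surface_radius_nm
        for d_nm in (150.0, 500.0, 2000.0, 8000.0):
            idx = grid.shell_index(d_nm)
            r_res = model.range_g_cm2[-1]
            path_um = d_nm * 1e-3
            r_left = np.interp(e0, model.energy_kev, model.range_g_cm2) - path_um * 1e-4
            e_here = float(np.exp(np.interp(np.log(r_left), model._log_r, model._log_e)))
            s_kev_um = model.stopping_kev_per_um(e_here)
            r_nm = r0 + d_nm
            # keV per nm^3 per electron -> Gy
            dose_expect = (
                s_kev_um * 1e-3 / (4.0 * np.pi * r_nm**2) * 1.602176634e-16 / 1e-24
            )
            assert dose[idx] == pytest.approx(dose_expect, rel=0.10)
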