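"""Scoring grids, dose accounting, DEF statistics, electron spectra."""

import numpy as np
import pytest

from nanodef import constants as const
from nanodef import scoring as SC
from nanodef import sources as S


class TestRadialShellGrid:
    def test_three_zone_scheme(self):
        g = SC.RadialShellGrid()
        widths = g.widths_nm()
        assert g.n_shells == 150 + 180 + 80
        assert np.all(widths[:150] == 1.0)
        assert np.all(widths[150:330] == 10.0)
        assert np.all(widths[330:] == 100.0)
        assert g.edges_nm[0] == 0.0
        assert g.edges_nm[-1] == 9950.0

    def test_shell_index(self):
        g = SC.RadialShellGrid()
        assert g.shell_index(0.5) == 0
        assert g.shell_index(149.5) == 149
        assert g.shell_index(155.0) == 150
        assert g.shell_index(9949.0) == 409
        assert g.shell_index(10_000.0) == -1

    def test_mass_dose_bookkeeping_identity(self):
        """Sum over shells of mass x dose returns the scored energy exactly."""
        g = SC.RadialShellGrid()
        prof = SC.ShellDoseProfile(grid=g)
        rng = np.random.default_rng(0)
        total = 0.0
        for _ in range(50):
            prof.begin_history()
            for _ in range(20):
                r = 50.0 + rng.uniform(0.0, 9000.0)
                e = rng.uniform(0.1, 5.0)
                SC.score_deposit([r, 0.0, 0.0], e, prof)
                total += e
            prof.end_history()
        dose, _ = prof.dose_gy_per_source()
        back = (dose * g.shell_masses_g() * 1e-3 / const.KEV_TO_JOULE).sum() * prof.n_histories
        assert back == pytest.approx(total, rel=1e-12)


class TestScoreDeposit:
    def test_np_internal_excluded_from_water_dose(self):
        prof = SC.ShellDoseProfile(grid=SC.RadialShellGrid())
        prof.begin_history()
        SC.score_deposit([0.0, 0.0, 20.0], 5.0, prof)   # inside the NP
        SC.score_deposit([0.0, 0.0, 50.5], 1.0, prof)   # first 1-nm shell
        prof.end_history()
        assert prof.np_internal_kev == 5.0
        assert prof.sum_kev[0] == 1.0
        assert prof.sum_kev[1:].sum() == 0.0

    def test_outside_grid_ignored_in_shells(self):
        prof = SC.ShellDoseProfile(grid=SC.RadialShellGrid())
        prof.begin_history()
        SC.score_deposit([0.0, 0.0, 10_050.0], 3.0, prof)
        prof.end_history()
        assert prof.sum_kev.sum() == 0.0

    def test_region_tally(self):
        tally = SC.RegionDoseTally()
        tally.begin_history()
        SC.score_deposit([0.0, 0.0, 1000.0], 1.0, tally)    # nucleus (1 um)
        SC.score_deposit([0.0, 0.0, 4000.0], 2.0, tally)    # cytoplasm
        SC.score_deposit([0.0, 0.0, 8000.0], 4.0, tally)    # outside the cell
        tally.end_history()
        assert tally.sums[1] == 1.0
        assert tally.sums[0] == 2.0


def _toy_profile(energies_per_history, grid=None):
    grid = grid or SC.RadialShellGrid()
    prof = SC.ShellDoseProfile(grid=grid)
    rng = np.random.default_rng(1)
    for e in energies_per_history:
        prof.begin_history()
        SC.score_deposit([0.0, 0.0, 55.0], e, prof)
        SC.score_deposit([0.0, 0.0, 1000.0], e * 0.5, prof)
        prof.end_history()
    return prof


class TestDEF:
    def test_identical_profiles_give_unity(self):
        p = _toy_profile([1.0, 2.0, 3.0])
        for lo, hi, r in SC.def_curve(p, p):
            assert r.value == pytest.approx(1.0)
        assert SC.integrated_def(p, p).value == pytest.approx(1.0)

    def test_doubled_numerator(self):
        a = _toy_profile([2.0, 4.0, 6.0])
        b = _toy_profile([1.0, 2.0, 3.0])
        for lo, hi, r in SC.def_curve(a, b):
            assert r.value == pytest.approx(2.0)
        assert SC.integrated_def(a, b).value == pytest.approx(2.0)

    def test_single_shell_toy_ratio(self):
        """Energy sums (4, 2) on a one-shell grid give DEF = 2."""
        grid = SC.RadialShellGrid(edges_nm=np.array([1.0, 9950.0]))
        a = SC.ShellDoseProfile(grid=grid)
        b = SC.ShellDoseProfile(grid=grid)
        for prof, e in ((a, 4.0), (b, 2.0)):
            prof.begin_history()
            SC.score_deposit([0.0, 0.0, 500.0], e, prof)
            prof.end_history()
        assert SC.integrated_def(a, b).value == pytest.approx(2.0)

    def test_grid_mismatch_raises(self):
        a = _toy_profile([1.0])
        b = SC.ShellDoseProfile(grid=SC.RadialShellGrid(edges_nm=np.array([0.0, 1.0, 2.0])))
        with pytest.raises(ValueError):
            SC.def_curve(a, b)

    def test_zero_denominator_shells_skipped(self):
        a = _toy_profile([1.0, 2.0])
        empty = SC.ShellDoseProfile(grid=SC.RadialShellGrid())
        empty.begin_history()
        SC.score_deposit([0.0, 0.0, 55.0], 1.0, empty)
        empty.end_history()
        curve = SC.def_curve(a, empty)
        assert len(curve) == 1  # only the populated shell is reported

    def test_error_propagation_first_order(self):
        r = SC.DEFResult(2.0, 0.1, 4.0, 2.0, "x")
        assert r.within(2.15, n_sigma=2)
        assert not r.within(2.5, n_sigma=2)


class TestSurfaceSpectrum:
    def test_empty_phase_space(self):
        phsp = S.make_toy_phase_space(0)
        tal = SC.surface_spectrum(phsp)
        assert tal.total_per_photon == 0.0

    def test_counts_per_source_photon(self):
        phsp = S.make_toy_phase_space(100, energy_kev=10.25, seed=2)
        phsp.header["history_count"] = 200
        tal = SC.surface_spectrum(phsp, bin_width_kev=0.5)
        assert tal.total_per_photon == pytest.approx(0.5)
        peak_bin = np.argmax(tal.counts_per_photon)
        assert tal.edges_kev[peak_bin] == pytest.approx(10.0)

    def test_au_100kev_photopeak_near_19kev(self, two_step_run):
        """The K-shell photoelectron line sits at 100 keV - K binding."""
        result = two_step_run("solid-gold", 100.0)
        tal = result.tallies["spectrum"]["solid-gold"]
        counts = tal.counts_per_photon
        mids = 0.5 * (tal.edges_kev[:-1] + tal.edges_kev[1:])
        window = (mids > 15.0) & (mids < 25.0)
        peak = mids[window][np.argmax(counts[window])]
        assert peak == pytest.approx(19.3, abs=1.0)


class TestWnpSelfConsistency:
    def test_wnp_vs_wnp_def_is_unity(self, two_step_run):
        """Two independent water-NP runs give integrated DEF = 1 within 2 sigma."""
        a = two_step_run("water", 50.0)
        b = two_step_run("water", 50.0, 6000, 977)  # different seed
        r = SC.integrated_def(a.profiles["water"], b.profiles["water"])
        assert abs(r.value - 1.0) <= 2.5 * r.stderr
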