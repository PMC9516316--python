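"""Cross sections, stopping power / ranges, Compton sampling, relaxation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from nanodef.materials import GOLD, MAGNETITE, WATER
from nanodef import physics as P
from nanodef.physics.compton import compton_energy_bounds_kev
from nanodef.physics.relaxation import RELAXATION_DATA


class TestInterpolation:
    @pytest.mark.parametrize("element", ["H", "O", "Fe", "Au"])
    def test_nodes_reproduced_exactly(self, element):
        e, v = P.element_pe_grid(element)
        out = P.mu_pe_element(element, e)
        assert np.allclose(out, v, rtol=1e-12)

    def test_au_k_edge_discontinuity(self):
        """The photoelectric coefficient jumps upward across the K edge."""
        assert P.mu(GOLD, 85.0, "photoelectric") > P.mu(GOLD, 79.0, "photoelectric")

    def test_total_is_sum_of_channels(self):
        for mat in (WATER, GOLD, MAGNETITE):
            for e in (5.0, 50.0, 500.0):
                tot = P.mu(mat, e, "total")
                parts = P.mu(mat, e, "photoelectric") + P.mu(mat, e, "compton")
                assert tot == pytest.approx(parts, rel=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            P.mu(WATER, 0.5)
        with pytest.raises(ValueError):
            P.mu(WATER, 1200.0)

    def test_photoelectric_ordering_au_magnetite_water(self):
        """Gold > magnetite > water per unit mass across the transport range.

        Tested above 2 keV: just below gold's M edges (~1 keV) iron's
        photoelectric coefficient per gram genuinely exceeds gold's, a real
        feature of the standard compilations, irrelevant at beam energies.
        """
        grid = np.geomspace(2.0, 900.0, 200)
        au = P.mu(GOLD, grid, "photoelectric")
        mag = P.mu(MAGNETITE, grid, "photoelectric")
        wat = P.mu(WATER, grid, "photoelectric")
        assert np.all(au > mag)
        assert np.all(mag > wat)


class TestStopping:
    def test_water_stopping_matches_standard_value(self):
        # liquid water collision stopping power at 10 keV, MeV cm^2/g
        assert P.collision_stopping_power(WATER, 10.0) == pytest.approx(22.56, rel=0.01)

    def test_range_energy_anchor(self):
        """An electron stopping in 9.95 um of water starts near 21.4 keV."""
        assert P.energy_from_range(9.95) == pytest.approx(21.4, rel=0.05)

    def test_mutual_inverse_round_trip(self):
        for r_um in (0.5, 2.0, 5.0, 20.0):
            assert P.csda_range(P.energy_from_range(r_um)) == pytest.approx(r_um, rel=5e-3)

    def test_range_against_independent_quadrature(self):
        """Table integration agrees with adaptive quadrature of 1/S."""
        model = P.water_stopping_model()

        def inv_s(e_kev):
            s = P.collision_stopping_power(WATER, e_kev) * 1e3  # keV cm^2/g
            return 1.0 / s

        r, _ = integrate.quad(inv_s, model.cutoff_kev, 10.0, limit=200)
        assert model.csda_range_um(10.0) == pytest.approx(r * 1e4, rel=0.05)

    def test_range_strictly_increasing(self):
        m = P.water_stopping_model()
        assert np.all(np.diff(m.range_g_cm2) > 0)


class TestKleinNishina:
    def test_minimum_scattered_energy_50kev(self):
        lo, hi = compton_energy_bounds_kev(50.0)
        assert lo == pytest.approx(41.82, abs=0.01)
        assert hi == 50.0

    def test_samples_respect_kinematics(self, rng):
        """Every sample satisfies the Compton energy-angle relation."""
        E = 80.0
        for _ in range(2000):
            e_sc, theta = P.klein_nishina_sample(E, rng)
            expect = E / (1.0 + (E / 511.0) * (1.0 - math.cos(theta)))
            assert e_sc == pytest.approx(expect, abs=1e-9)
            assert compton_energy_bounds_kev(E)[0] - 1e-9 <= e_sc <= E + 1e-9

    def test_low_energy_limit_is_thomson(self, rng):
        """As E -> 0 the angular distribution approaches 1 + cos^2(theta)."""
        E = 0.05
        cos_t = np.array([math.cos(P.klein_nishina_sample(E, rng)[1]) for _ in range(20000)])

        def thomson_cdf(c):
            # integral of (1 + x^2) dx from -1 to c, normalised by 8/3
            return (c + c**3 / 3.0 + 4.0 / 3.0) / (8.0 / 3.0)

        p = stats.kstest(cos_t, thomson_cdf).pvalue
        assert p > 0.01

    def test_mean_scattered_energy_matches_integral(self, rng):
        """Empirical mean E' agrees with the numerically integrated expectation."""
        E = 100.0
        a = E / 511.0
        eps_min = 1.0 / (1.0 + 2.0 * a)

        def f(eps):
            cost = 1.0 - (1.0 / eps - 1.0) / a
            return eps + 1.0 / eps - (1.0 - cost**2)

        norm, _ = integrate.quad(f, eps_min, 1.0)
        mean_eps, _ = integrate.quad(lambda e: e * f(e), eps_min, 1.0)
        expected = E * mean_eps / norm
        n = 100_000
        samples = np.array([P.klein_nishina_sample(E, rng)[0] for _ in range(n)])
        se = samples.std() / math.sqrt(n)
        assert abs(samples.mean() - expected) < 3 * se


class TestRelaxation:
    def test_energy_conservation_exact(self, rng):
        for element, shell in (("Au", "K"), ("Au", "L"), ("Fe", "K")):
            b = RELAXATION_DATA[element].binding_kev[shell]
            for _ in range(200):
                out = P.relax_vacancy(element, shell, rng)
                total = sum(q.energy_kev for q in out.quanta) + out.local_deposit_kev
                assert total == pytest.approx(b, abs=1e-12)

    def test_au_k_fluorescence_energy(self, rng):
        """The K-L transition photon carries K minus L binding (K-alpha proxy)."""
        data = RELAXATION_DATA["Au"]
        expect = data.binding_kev["K"] - data.binding_kev["L"]
        photons = []
        for _ in range(200):
            out = P.relax_vacancy("Au", "K", rng)
            if out.quanta and out.quanta[0].kind == "photon":
                photons.append(out.quanta[0].energy_kev)
        assert photons  # omega_K = 0.96, fluorescence dominates
        assert np.allclose(photons, expect)

    def test_auger_toggle_off(self, rng):
        out = P.relax_vacancy("Au", "K", rng, auger_enabled=False)
        assert out.quanta == ()
        assert out.local_deposit_kev == RELAXATION_DATA["Au"].binding_kev["K"]

    def test_au_l_auger_below_14_kev(self, rng):
        """Auger electrons from L vacancies stay in the few-keV range."""
        for _ in range(500):
            out = P.relax_vacancy("Au", "L", rng)
            for q in out.quanta:
                if q.kind == "electron":
                    assert q.energy_kev <= 14.0

    def test_unknown_element_raises(self, rng):
        with pytest.raises(KeyError):
            P.relax_vacancy("Xx", "K", rng)
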