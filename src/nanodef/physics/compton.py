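"""Compton scattering: Klein-Nishina total cross section and sampling.

Scattering is treated per free electron (incoherent scattering function
omitted), which is accurate to a few percent above ~20 keV.  The sampler
draws the scattered photon energy by rejection against the Klein-Nishina
energy distribution and returns the polar angle fixed by Compton kinematics.
"""

from __future__ import annotations

import math

import numpy as np

from .. import constants as const

_TWO_PI_RE2 = 2.0 * math.pi * const.CLASSICAL_ELECTRON_RADIUS_CM**2


def kn_total_cross_section_cm2(energy_kev):
    """Klein-Nishina total cross section per electron (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / const.ELECTRON_REST_KEV
    t = 1.0 + 2.0 * a
    log_t = np.log(t)
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - log_t / a)
    term2 = log_t / (2.0 * a)
    term3 = (1.0 + 3.0 * a) / t**2
    out = _TWO_PI_RE2 * (term1 + term2 - term3)
    return float(out) if np.isscalar(energy_kev) else out


def compton_energy_bounds_kev(energy_kev: float) -> tuple:
    """(min, max) scattered photon energy at incident energy E."""
    a = energy_kev / const.ELECTRON_REST_KEV
    return energy_kev / (1.0 + 2.0 * a), energy_kev


def klein_nishina_sample(energy_kev: float, rng: np.random.Generator):
    """Sample (scattered energy keV, polar angle rad) from Klein-Nishina.

    Rejection sampling of eps = E'/E on [1/(1+2a), 1] with density
    proportional to eps + 1/eps - sin^2(theta); the angle follows from the
    Compton relation, so every sample satisfies it identically.
    """
    a = energy_kev / const.ELECTRON_REST_KEV
    eps_min = 1.0 / (1.0 + 2.0 * a)
    bound = eps_min + 1.0 / eps_min  # >= eps + 1/eps >= f(eps)
    while True:
        eps = eps_min + (1.0 - eps_min) * rng.random()
        cos_t = 1.0 - (1.0 / eps - 1.0) / a if a > 0 else 1.0
        sin2 = 1.0 - cos_t * cos_t
        f = eps + 1.0 / eps - sin2
        if rng.random() * bound <= f:
            cos_t = min(1.0, max(-1.0, cos_t))
            return energy_kev * eps, math.acos(cos_t)


def compton_electron(energy_kev: float, scattered_kev: float, theta: float):
    """(electron kinetic energy keV, electron polar angle rad) by momentum balance."""
    t_e = energy_kev - scattered_kev
    # p_e sin(phi) = E' sin(theta); p_e cos(phi) = E - E' cos(theta)   (units keV/c)
    py = scattered_kev * math.sin(theta)
    px = energy_kev - scattered_kev * math.cos(theta)
    return t_e, math.atan2(py, px)
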