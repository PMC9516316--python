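"""Photon interaction coefficients over 1-900 keV.

Photoelectric mass attenuation comes from the packaged per-element table
(log-log interpolated, with duplicated nodes preserving absorption edges);
the incoherent (Compton) channel is the analytic Klein-Nishina cross section
per free electron scaled by the material electron density.  Rayleigh
scattering is omitted (no energy deposition; negligible angular diffusion at
the spatial scales scored here).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .. import constants as const
from ..materials import Material
from .compton import kn_total_cross_section_cm2

_EDGE_NUDGE = 1e-9  # relative offset distinguishing below/above an edge

ELEMENT_EDGES_KEV = {
    # shell binding energies used for photoelectron kinematics (keV)
    "H": {"K": 0.0136},
    "O": {"K": 0.543},
    "Fe": {"K": 7.112, "L": 0.708},
    "Au": {"K": 80.725, "L": 11.919, "M": 2.21},
}


def _load_photoelectric():
    data = {}
    ref = resources.files("nanodef.physics").joinpath("data/photoelectric.csv")
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            data.setdefault(row["element"], []).append(
                (float(row["energy_kev"]), float(row["mu_pe_cm2_per_g"]))
            )
    tables = {}
    for sym, rows in data.items():
        e = np.array([r[0] for r in rows])
        v = np.array([r[1] for r in rows])
        # separate duplicated edge nodes so interpolation is single valued
        for i in range(1, len(e)):
            if e[i] == e[i - 1]:
                e[i - 1] *= 1.0 - _EDGE_NUDGE
        tables[sym] = (np.log(e), np.log(v))
    return tables


_PE_TABLES = _load_photoelectric()


def mu_pe_element(element: str, energy_kev) -> np.ndarray | float:
    """Photoelectric mass attenuation (cm^2/g) of an element, log-log interpolated."""
    loge, logv = _PE_TABLES[element]
    E = np.asarray(energy_kev, dtype=float)
    tol = 1e-9
    if np.any(E < const.ENERGY_GRID_MIN_KEV * (1 - tol)) or np.any(
        E > const.ENERGY_GRID_MAX_KEV * (1 + tol)
    ):
        raise ValueError(f"energy outside table support [1, 900] keV: {energy_kev}")
    out = np.exp(np.interp(np.log(E), loge, logv))
    return float(out) if np.isscalar(energy_kev) else out


@dataclass(frozen=True)
class CrossSectionSet:
    """Per-material photon coefficients on a shared support of 1-900 keV."""

    material: Material

    def mu(self, energy_kev, channel: str = "total"):
        """Mass attenuation coefficient (cm^2/g) for a channel."""
        if channel == "photoelectric":
            out = 0.0
            for sym, frac in self.material.composition:
                out = out + frac * mu_pe_element(sym, energy_kev)
            return out
        if channel == "compton":
            E = np.asarray(energy_kev, dtype=float)
            if np.any(E < const.ENERGY_GRID_MIN_KEV) or np.any(E > const.ENERGY_GRID_MAX_KEV):
                raise ValueError(f"energy outside table support: {energy_kev}")
            sigma = kn_total_cross_section_cm2(E)
            out = self.material.electrons_per_gram * sigma
            return float(out) if np.isscalar(energy_kev) else out
        if channel == "total":
            return self.mu(energy_kev, "photoelectric") + self.mu(energy_kev, "compton")
        raise ValueError(f"unknown channel {channel!r}")

    def mu_linear(self, energy_kev, channel: str = "total"):
        """Linear attenuation coefficient (1/cm)."""
        return self.material.density * self.mu(energy_kev, channel)


def mu(material: Material, energy_kev, channel: str = "total"):
    """Mass attenuation coefficient (cm^2/g) of `material` at `energy_kev`."""
    return CrossSectionSet(material).mu(energy_kev, channel)


def element_pe_grid(element: str):
    """(energy, coefficient) nodes of the embedded photoelectric table."""
    loge, logv = _PE_TABLES[element]
    return np.exp(loge), np.exp(logv)
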