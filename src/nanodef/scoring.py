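"""Dose accumulation and dose-enhancement statistics.

Doses are energy over the WATER mass of the scoring region (deposits inside
nanoparticle volumes are tallied separately and excluded), reported in Gy per
source particle.  Uncertainties use the history-by-history estimator: for a
per-history deposit x, se(mean) = sqrt((<x^2> - <x>^2) / N).  The dose
enhancement factor (DEF) is the ratio of doses with and without the
nanoparticle(s), with first-order error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as const


def radial_shell_edges_nm() -> np.ndarray:
    """Three-zone shell edges as distance from the NP surface (nm).

    1 nm steps on [0, 150], 10 nm on (150, 1950], 100 nm on (1950, 9950].
    """
    return np.concatenate(
        [
            np.arange(0.0, 150.0 + 0.5, 1.0),
            np.arange(160.0, 1950.0 + 0.5, 10.0),
            np.arange(2050.0, 9950.0 + 0.5, 100.0),
        ]
    )


@dataclass
class RadialShellGrid:
    """Concentric scoring shells around a nanoparticle surface."""

    surface_radius_nm: float = const.NP_RADIUS_NM
    edges_nm: np.ndarray = field(default_factory=radial_shell_edges_nm)

    def __post_init__(self):
        self.edges_nm = np.asarray(self.edges_nm, dtype=float)
        if np.any(np.diff(self.edges_nm) <= 0):
            raise ValueError("shell edges must be strictly increasing")

    @property
    def n_shells(self) -> int:
        return len(self.edges_nm) - 1

    def shell_index(self, distance_nm: float) -> int:
        """Index of the shell containing a surface distance, or -1 outside."""
        if distance_nm < self.edges_nm[0] or distance_nm >= self.edges_nm[-1]:
            return -1
        return int(np.searchsorted(self.edges_nm, distance_nm, side="right")) - 1

    def shell_masses_g(self) -> np.ndarray:
        r = self.surface_radius_nm + self.edges_nm
        vol_nm3 = 4.0 / 3.0 * math.pi * (r[1:] ** 3 - r[:-1] ** 3)
        return vol_nm3 * 1e-21 * const.DENSITY_WATER

    def widths_nm(self) -> np.ndarray:
        return np.diff(self.edges_nm)


def _mean_se(sum_x: np.ndarray, sum_x2: np.ndarray, n: int):
    mean = sum_x / n
    var = np.maximum(sum_x2 / n - mean**2, 0.0) / n
    return mean, np.sqrt(var)


@dataclass
class ShellDoseProfile:
    """Per-shell deposited energy with history-by-history uncertainties."""

    grid: RadialShellGrid
    sum_kev: np.ndarray = None
    sum_kev2: np.ndarray = None
    n_histories: int = 0
    np_internal_kev: float = 0.0
    # per-history accumulators for the fixed integration range 1-9950 nm
    int_sum_kev: float = 0.0
    int_sum_kev2: float = 0.0
    int_range_nm: tuple = (1.0, 9950.0)
    label: str = ""

    def __post_init__(self):
        n = self.grid.n_shells
        if self.sum_kev is None:
            self.sum_kev = np.zeros(n)
        if self.sum_kev2 is None:
            self.sum_kev2 = np.zeros(n)
        self._scratch = np.zeros(n)
        self._touched: list = []
        lo, hi = self.int_range_nm
        self._int_mask = (self.grid.edges_nm[:-1] >= lo) & (self.grid.edges_nm[1:] <= hi)

    # --- streaming interface (reference engine) ---
    def begin_history(self):
        for idx in self._touched:
            self._scratch[idx] = 0.0
        self._touched.clear()

    def add(self, site_nm, energy_kev, weight=1.0):
        r = float(np.linalg.norm(site_nm))
        d = r - self.grid.surface_radius_nm
        if d < 0:
            self.np_internal_kev += energy_kev * weight
            return
        idx = self.grid.shell_index(d)
        if idx < 0:
            return
        if self._scratch[idx] == 0.0:
            self._touched.append(idx)
        self._scratch[idx] += energy_kev * weight

    def end_history(self):
        self.n_histories += 1
        int_x = 0.0
        for idx in self._touched:
            x = self._scratch[idx]
            self.sum_kev[idx] += x
            self.sum_kev2[idx] += x * x
            if self._int_mask[idx]:
                int_x += x
        self.int_sum_kev += int_x
        self.int_sum_kev2 += int_x * int_x

    # --- results ---
    @classmethod
    def from_arrays(cls, grid, sum_kev, sum_kev2, n_histories, np_internal_kev=0.0,
                    int_sum_kev=0.0, int_sum_kev2=0.0, label=""):
        out = cls(grid=grid, sum_kev=np.asarray(sum_kev, dtype=float),
                  sum_kev2=np.asarray(sum_kev2, dtype=float), n_histories=int(n_histories),
                  np_internal_kev=float(np_internal_kev), int_sum_kev=float(int_sum_kev),
                  int_sum_kev2=float(int_sum_kev2), label=label)
        return out

    def dose_gy_per_source(self):
        """(dose, stderr) arrays in Gy per source particle."""
        if self.n_histories == 0:
            raise ValueError("no histories scored")
        mean, se = _mean_se(self.sum_kev, self.sum_kev2, self.n_histories)
        scale = const.KEV_TO_JOULE / (self.grid.shell_masses_g() * 1e-3)
        return mean * scale, se * scale

    def integrated_energy(self):
        """(mean, se) of per-history energy (keV) in the integration range."""
        if self.n_histories == 0:
            raise ValueError("no histories scored")
        m, s = _mean_se(np.array([self.int_sum_kev]), np.array([self.int_sum_kev2]), self.n_histories)
        return float(m[0]), float(s[0])

    def to_dataframe(self) -> pd.DataFrame:
        dose, se = self.dose_gy_per_source()
        return pd.DataFrame(
            {
                "shell_lo_nm": self.grid.edges_nm[:-1],
                "shell_hi_nm": self.grid.edges_nm[1:],
                "dose_gy_per_source": dose,
                "stderr": se,
            }
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class RegionDoseTally:
    """Cytoplasm / nucleus dose accumulator for the cell model."""

    cell_radius_um: float = const.CELL_RADIUS_UM
    nucleus_radius_um: float = const.NUCLEUS_RADIUS_UM
    np_volume_um3: float = 0.0   # total NP volume excluded from cytoplasm water
    n_histories: int = 0
    sums: np.ndarray = None      # [cytoplasm, nucleus]
    sums2: np.ndarray = None
    np_internal_kev: float = 0.0
    label: str = ""

    REGIONS = ("cytoplasm", "nucleus")

    def __post_init__(self):
        if self.sums is None:
            self.sums = np.zeros(2)
        if self.sums2 is None:
            self.sums2 = np.zeros(2)
        self._scratch = np.zeros(2)

    def region_masses_g(self) -> np.ndarray:
        v_nuc = 4.0 / 3.0 * math.pi * self.nucleus_radius_um**3
        v_cyt = 4.0 / 3.0 * math.pi * self.cell_radius_um**3 - v_nuc - self.np_volume_um3
        return np.array([v_cyt, v_nuc]) * 1e-12 * const.DENSITY_WATER

    def begin_history(self):
        self._scratch[:] = 0.0

    def add(self, site_nm, energy_kev, weight=1.0):
        r = float(np.linalg.norm(site_nm)) * 1e-3  # um
        if r <= self.nucleus_radius_um:
            self._scratch[1] += energy_kev * weight
        elif r <= self.cell_radius_um:
            self._scratch[0] += energy_kev * weight

    def end_history(self):
        self.n_histories += 1
        self.sums += self._scratch
        self.sums2 += self._scratch**2

    @classmethod
    def from_arrays(cls, sums, sums2, n_histories, np_volume_um3=0.0,
                    np_internal_kev=0.0, label="", **geom):
        return cls(sums=np.asarray(sums, dtype=float), sums2=np.asarray(sums2, dtype=float),
                   n_histories=int(n_histories), np_volume_um3=float(np_volume_um3),
                   np_internal_kev=float(np_internal_kev), label=label, **geom)

    def dose_gy_per_source(self):
        if self.n_histories == 0:
            raise ValueError("no histories scored")
        mean, se = _mean_se(self.sums, self.sums2, self.n_histories)
        scale = const.KEV_TO_JOULE / (self.region_masses_g() * 1e-3)
        return mean * scale, se * scale


@dataclass
class ElectronSpectrumTally:
    """Histogram of electrons crossing the NP surface outward, per source photon."""

    edges_kev: np.ndarray
    counts_per_photon: np.ndarray
    auger_label: str = "auger-on"
    label: str = ""

    def __post_init__(self):
        self.edges_kev = np.asarray(self.edges_kev, dtype=float)
        self.counts_per_photon = np.asarray(self.counts_per_photon, dtype=float)
        if np.any(np.diff(self.edges_kev) <= 0):
            raise ValueError("bin edges must be increasing")
        if np.any(self.counts_per_photon < 0):
            raise ValueError("negative counts")

    @property
    def total_per_photon(self) -> float:
        return float(self.counts_per_photon.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_keV": self.edges_kev[:-1],
                "bin_hi_keV": self.edges_kev[1:],
                "electrons_per_photon": self.counts_per_photon,
            }
        )


def surface_spectrum(phase_space, bin_width_kev: float = 0.5, auger_label: str = "auger-on"):
    """Bin outward surface-crossing electron records into an energy spectrum."""
    n_source = max(phase_space.n_source, 1)
    energies = phase_space.energy_kev[phase_space.kind == 1]
    weights = phase_space.weight[phase_space.kind == 1]
    e_max = float(energies.max()) if len(energies) else bin_width_kev
    n_bins = max(1, int(math.ceil(e_max / bin_width_kev)))
    edges = bin_width_kev * np.arange(n_bins + 1)
    counts, _ = np.histogram(energies, bins=edges, weights=weights)
    return ElectronSpectrumTally(edges, counts / n_source, auger_label=auger_label,
                                 label=phase_space.header.get("np_model", ""))


@dataclass(frozen=True)
class DEFResult:
    """Dose-enhancement factor with propagated uncertainty."""

    value: float
    stderr: float
    numerator: float
    denominator: float
    scope: str

    def within(self, expected: float, n_sigma: float = 2.0) -> bool:
        return abs(self.value - expected) <= n_sigma * self.stderr


def _ratio(num, num_se, den, den_se, scope) -> DEFResult:
    if den <= 0:
        raise ZeroDivisionError(f"zero denominator dose in {scope}")
    val = num / den
    se = math.hypot(num_se / den, num * den_se / den**2)
    return DEFResult(val, se, num, den, scope)


def score_deposit(site_nm, energy_kev, accumulator, weight: float = 1.0):
    """Push one energy deposit into a profile or region tally."""
    accumulator.add(site_nm, energy_kev, weight)
    return accumulator


def def_curve(with_np: ShellDoseProfile, without_np: ShellDoseProfile):
    """Shell-wise DEF; shells with zero denominator dose are skipped.

    Returns a list of (shell_lo_nm, shell_hi_nm, DEFResult).
    """
    if not np.array_equal(with_np.grid.edges_nm, without_np.grid.edges_nm):
        raise ValueError("profiles scored on different grids")
    d1, s1 = with_np.dose_gy_per_source()
    d0, s0 = without_np.dose_gy_per_source()
    out = []
    lo, hi = with_np.grid.edges_nm[:-1], with_np.grid.edges_nm[1:]
    for i in range(with_np.grid.n_shells):
        if d0[i] <= 0:
            continue
        out.append((lo[i], hi[i], _ratio(d1[i], s1[i], d0[i], s0[i], f"shell {lo[i]:g}-{hi[i]:g} nm")))
    return out


def integrated_def(with_np: ShellDoseProfile, without_np: ShellDoseProfile) -> DEFResult:
    """DEF of the energy integrated over 1-9950 nm from the NP surface.

    Shell masses are common to both arms, so the mass-weighted dose ratio
    equals the energy ratio on the common grid.
    """
    if not np.array_equal(with_np.grid.edges_nm, without_np.grid.edges_nm):
        raise ValueError("profiles scored on different grids")
    e1, s1 = with_np.integrated_energy()
    e0, s0 = without_np.integrated_energy()
    return _ratio(e1, s1, e0, s0, "integrated 1-9950 nm")


def region_def(with_np: RegionDoseTally, without_np: RegionDoseTally, region: str) -> DEFResult:
    idx = RegionDoseTally.REGIONS.index(region)
    d1, s1 = with_np.dose_gy_per_source()
    d0, s0 = without_np.dose_gy_per_source()
    return _ratio(d1[idx], s1[idx], d0[idx], s0[idx], region)
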