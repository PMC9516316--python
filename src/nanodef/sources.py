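"""Synthetic photon spectra and phase-space file I/O.

Provides an Ir-192-like high-dose-rate brachytherapy spectrum (principal
gamma lines plus a low-energy scattered continuum emulating transmission
through ~2 cm of water and the source encapsulation), inverse-CDF energy
sampling, and a self-describing columnar text format for electron
phase-space records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# principal Ir-192 gamma lines (keV) and relative emission intensities (%)
IR192_LINES = (
    (205.79, 3.34),
    (295.96, 28.71),
    (308.46, 29.70),
    (316.51, 82.86),
    (468.07, 47.84),
    (484.58, 3.19),
    (588.58, 4.52),
    (604.41, 8.20),
    (612.46, 5.34),
    (884.54, 0.29),
)


class SpectrumError(ValueError):
    pass


class PhaseSpaceParseError(ValueError):
    pass


@dataclass
class EnergySpectrum:
    """Histogram spectrum: bin edges (keV) and normalized per-bin weights."""

    edges_kev: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.edges_kev = np.asarray(self.edges_kev, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.edges_kev) != len(self.weights) + 1:
            raise SpectrumError("need len(edges) == len(weights) + 1")
        if np.any(np.diff(self.edges_kev) <= 0):
            raise SpectrumError("bin edges must be strictly increasing")
        if np.any(self.weights < 0):
            raise SpectrumError("negative bin weight")
        total = self.weights.sum()
        if total <= 0:
            raise SpectrumError("spectrum has no weight")
        self.weights = self.weights / total
        self._cdf = np.concatenate([[0.0], np.cumsum(self.weights)])
        self._cdf[-1] = 1.0

    @property
    def mean_energy_kev(self) -> float:
        mids = 0.5 * (self.edges_kev[:-1] + self.edges_kev[1:])
        return float(mids @ self.weights)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("bin_lo_keV,bin_hi_keV,weight\n")
            for lo, hi, w in zip(self.edges_kev[:-1], self.edges_kev[1:], self.weights):
                fh.write(f"{lo:.9g},{hi:.9g},{w:.12g}\n")

    @classmethod
    def from_csv(cls, path, label="") -> "EnergySpectrum":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if rows.shape[1] != 3:
            raise SpectrumError(f"expected 3 columns in {path}")
        lo, hi, w = rows[:, 0], rows[:, 1], rows[:, 2]
        if not np.allclose(lo[1:], hi[:-1]):
            raise SpectrumError("bins must be contiguous")
        return cls(np.concatenate([lo, hi[-1:]]), w, label=label or str(path))


def delta_spectrum(energy_kev: float, width_kev: float = 1e-6) -> EnergySpectrum:
    """Single-bin spectrum; degenerates a spectrum source to monoenergetic."""
    return EnergySpectrum(
        np.array([energy_kev - width_kev / 2, energy_kev + width_kev / 2]),
        np.array([1.0]),
        label=f"delta-{energy_kev:g}keV",
    )


def make_ir192_like_spectrum(
    resolution_kev: float = 2.0,
    scatter_fraction: float = 0.30,
    seed: int = 0,
    e_min_kev: float = 60.0,
    e_max_kev: float = 900.0,
) -> EnergySpectrum:
    """Ir-192-like spectrum: gamma lines plus a scattered continuum.

    Lines are broadened into histogram bins of `resolution_kev`; a continuum
    carrying `scatter_fraction` of the probability mass models photons
    down-scattered in ~2 cm of water / the steel capsule, rising from the
    support minimum, peaking near 100-200 keV and fading towards the Compton
    edges of the main lines (~300 keV).  Deterministic for fixed arguments.
    """
    if resolution_kev <= 0:
        raise SpectrumError("resolution must be positive")
    if not 0.0 <= scatter_fraction < 1.0:
        raise SpectrumError("scatter_fraction must lie in [0, 1)")
    del seed  # generation is deterministic; kept for interface stability
    n_bins = int(math.ceil((e_max_kev - e_min_kev) / resolution_kev))
    edges = e_min_kev + resolution_kev * np.arange(n_bins + 1)
    weights = np.zeros(n_bins)
    total_line = sum(i for _, i in IR192_LINES)
    for e_line, intensity in IR192_LINES:
        idx = min(n_bins - 1, max(0, int((e_line - e_min_kev) / resolution_kev)))
        weights[idx] += (1.0 - scatter_fraction) * intensity / total_line
    if scatter_fraction > 0:
        mids = 0.5 * (edges[:-1] + edges[1:])
        # gamma-like hump: x^2 exp(-x/70) on [e_min, 300], zero above
        x = mids - e_min_kev
        cont = np.where(mids < 300.0, x**2 * np.exp(-x / 70.0), 0.0)
        if cont.sum() <= 0:
            raise SpectrumError("continuum support empty; widen the energy window")
        weights += scatter_fraction * cont / cont.sum()
    return EnergySpectrum(edges, weights, label=f"ir192-like/res{resolution_kev:g}")


def sample_energy(spectrum: EnergySpectrum, rng: np.random.Generator) -> float:
    """Inverse-CDF sample, uniform within the selected bin."""
    u = rng.random()
    idx = int(np.searchsorted(spectrum._cdf, u, side="right")) - 1
    idx = min(max(idx, 0), len(spectrum.weights) - 1)
    lo, hi = spectrum.edges_kev[idx], spectrum.edges_kev[idx + 1]
    return float(lo + (hi - lo) * rng.random())


def sample_energies(spectrum: EnergySpectrum, n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    idx = np.clip(np.searchsorted(spectrum._cdf, u, side="right") - 1, 0, len(spectrum.weights) - 1)
    lo = spectrum.edges_kev[idx]
    hi = spectrum.edges_kev[idx + 1]
    return lo + (hi - lo) * rng.random(n)


# ---------------------------------------------------------------------------
# phase-space records

PHSP_FORMAT_VERSION = "nanodef-phsp-1"
_PHSP_COLUMNS = ("x_nm", "y_nm", "z_nm", "ux", "uy", "uz", "energy_kev", "kind", "weight", "history")
_KIND_CODE = {"photon": 0, "electron": 1}
_KIND_NAME = {v: k for k, v in _KIND_CODE.items()}


@dataclass
class PhaseSpace:
    """Columnar particle records crossing a reference surface."""

    position_nm: np.ndarray      # (n, 3)
    direction: np.ndarray        # (n, 3), unit vectors
    energy_kev: np.ndarray       # (n,)
    kind: np.ndarray             # (n,) int codes, 1 = electron
    weight: np.ndarray           # (n,)
    history: np.ndarray          # (n,) source-history index
    header: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position_nm = np.atleast_2d(np.asarray(self.position_nm, dtype=float))
        self.direction = np.atleast_2d(np.asarray(self.direction, dtype=float))
        if self.position_nm.shape[1] == 0:
            self.position_nm = self.position_nm.reshape(0, 3)
            self.direction = self.direction.reshape(0, 3)
        self.energy_kev = np.asarray(self.energy_kev, dtype=float)
        self.kind = np.asarray(self.kind, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        self.history = np.asarray(self.history, dtype=int)
        n = len(self.energy_kev)
        if not (len(self.position_nm) == len(self.direction) == len(self.kind) == len(self.weight) == len(self.history) == n):
            raise ValueError("phase-space columns have inconsistent lengths")
        if n and np.any(np.abs((self.direction**2).sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")

    def __len__(self):
        return len(self.energy_kev)

    @property
    def n_source(self) -> int:
        return int(self.header.get("history_count", 0))


def write_phase_space(path, phsp: PhaseSpace) -> None:
    """Write records as documented text: '# key: value' header + 10 columns."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# format: {PHSP_FORMAT_VERSION}\n")
        for key, val in phsp.header.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: " + " ".join(_PHSP_COLUMNS) + "\n")
        for i in range(len(phsp)):
            x, y, z = (float(v) for v in phsp.position_nm[i])
            ux, uy, uz = (float(v) for v in phsp.direction[i])
            fh.write(
                f"{x!r} {y!r} {z!r} {ux!r} {uy!r} {uz!r} "
                f"{float(phsp.energy_kev[i])!r} {int(phsp.kind[i])} "
                f"{float(phsp.weight[i])!r} {int(phsp.history[i])}\n"
            )


def read_phase_space(path) -> PhaseSpace:
    """Lossless inverse of write_phase_space; parse errors name the line."""
    header: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != len(_PHSP_COLUMNS):
                raise PhaseSpaceParseError(
                    f"{path}: line {lineno}: expected {len(_PHSP_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise PhaseSpaceParseError(f"{path}: line {lineno}: {exc}") from exc
    if header.get("format") != PHSP_FORMAT_VERSION:
        raise PhaseSpaceParseError(f"{path}: missing or unknown format header")
    arr = np.array(rows, dtype=float).reshape(len(rows), len(_PHSP_COLUMNS))
    return PhaseSpace(
        position_nm=arr[:, 0:3],
        direction=arr[:, 3:6],
        energy_kev=arr[:, 6],
        kind=arr[:, 7].astype(int),
        weight=arr[:, 8],
        history=arr[:, 9].astype(int),
        header=header,
    )


def make_toy_phase_space(
    n: int,
    energy_kev=21.4,
    seed: int = 0,
    surface_radius_nm: float = 50.0,
) -> PhaseSpace:
    """Isotropic outward electrons on a sphere surface; unit-tests step 2.

    `energy_kev` may be a scalar (monoenergetic) or a callable rng -> keV.
    Every record satisfies position . direction >= 0.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    pos_dir = rng.normal(size=(n, 3))
    pos_dir /= np.linalg.norm(pos_dir, axis=1, keepdims=True) if n else 1.0
    pos = surface_radius_nm * pos_dir
    # outward-hemisphere directions around the surface normal
    d = rng.normal(size=(n, 3))
    if n:
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        flip = (d * pos_dir).sum(axis=1) < 0
        d[flip] -= 2.0 * (d[flip] * pos_dir[flip]).sum(axis=1, keepdims=True) * pos_dir[flip]
    if callable(energy_kev):
        energies = np.array([energy_kev(rng) for _ in range(n)])
    else:
        energies = np.full(n, float(energy_kev))
    return PhaseSpace(
        position_nm=pos.reshape(n, 3),
        direction=d.reshape(n, 3),
        energy_kev=energies,
        kind=np.ones(n, dtype=int),
        weight=np.ones(n),
        history=np.arange(n),
        header={
            "format": PHSP_FORMAT_VERSION,
            "np_model": "toy",
            "source": f"toy isotropic r={surface_radius_nm} nm",
            "seed": seed,
            "history_count": n,
        },
    )
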