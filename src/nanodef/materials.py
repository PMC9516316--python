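"""Materials, nanoparticle / cell geometry and concentration bookkeeping.

The three nanoparticle models studied are 100 nm spheres: solid gold, a
core-shell particle (60 nm magnetite core, 20 nm gold shell) and an all-water
null particle used as the dose-enhancement baseline.  Mass concentration in
the cytoplasm is converted to an integer particle count against the
whole-cell sphere volume, which is the convention that reproduces the
published count table exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as const


class InvalidGeometryError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    """Elemental mixture with a density.

    composition is a tuple of (element symbol, mass fraction); fractions must
    sum to one.
    """

    name: str
    density: float  # g/cm^3
    composition: tuple

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(frac for _, frac in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")
        for sym, frac in self.composition:
            if sym not in const.ATOMIC_NUMBER:
                raise ValueError(f"unknown element {sym!r}")
            if frac < 0:
                raise ValueError("negative mass fraction")

    @property
    def electrons_per_gram(self) -> float:
        """N_A * sum_i w_i Z_i / A_i."""
        return const.AVOGADRO * sum(
            frac * const.ATOMIC_NUMBER[sym] / const.ATOMIC_WEIGHT[sym]
            for sym, frac in self.composition
        )

    @property
    def z_over_a(self) -> float:
        return sum(
            frac * const.ATOMIC_NUMBER[sym] / const.ATOMIC_WEIGHT[sym]
            for sym, frac in self.composition
        )

    @property
    def mean_excitation_ev(self) -> float:
        """Bragg-additivity mean excitation energy (water uses the standard 75 eV)."""
        if self.name == "water":
            return const.MEAN_EXCITATION_WATER_EV
        num = sum(
            frac
            * const.ATOMIC_NUMBER[sym]
            / const.ATOMIC_WEIGHT[sym]
            * math.log(const.MEAN_EXCITATION_EV[sym])
            for sym, frac in self.composition
        )
        return math.exp(num / self.z_over_a)


WATER = Material("water", const.DENSITY_WATER, const.WATER_COMPOSITION)
GOLD = Material("gold", const.DENSITY_GOLD, const.GOLD_COMPOSITION)
MAGNETITE = Material("magnetite", const.DENSITY_MAGNETITE, const.MAGNETITE_COMPOSITION)

MATERIALS = {m.name: m for m in (WATER, GOLD, MAGNETITE)}


@dataclass(frozen=True)
class NanoparticleModel:
    """Concentric spherical layers; layers = ((outer radius nm, Material), ...)."""

    label: str
    layers: tuple

    def __post_init__(self):
        radii = [r for r, _ in self.layers]
        if not radii:
            raise InvalidGeometryError("nanoparticle needs at least one layer")
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])) or radii[0] <= 0:
            raise InvalidGeometryError(f"layer radii must be strictly increasing: {radii}")

    @property
    def radius_nm(self) -> float:
        return self.layers[-1][0]

    def material_at(self, r_nm: float) -> Material | None:
        """Material of the layer containing radius r (half-open: boundary -> inner)."""
        for outer, mat in self.layers:
            if r_nm <= outer:
                return mat
        return None

    def mass_mg(self) -> float:
        return np_mass(self)


def solid_gold_np() -> NanoparticleModel:
    return NanoparticleModel("solid-gold", ((const.NP_RADIUS_NM, GOLD),))


def core_shell_np() -> NanoparticleModel:
    return NanoparticleModel(
        "core-shell",
        ((const.CORE_RADIUS_NM, MAGNETITE), (const.NP_RADIUS_NM, GOLD)),
    )


def water_np() -> NanoparticleModel:
    return NanoparticleModel("water", ((const.NP_RADIUS_NM, WATER),))


NP_MODELS = {
    "solid-gold": solid_gold_np,
    "core-shell": core_shell_np,
    "water": water_np,
}


def np_mass(np_model: NanoparticleModel) -> float:
    """Nanoparticle mass in mg (sum of shell volumes times layer densities)."""
    mass_g = 0.0
    inner = 0.0
    for outer_nm, mat in np_model.layers:
        vol_cm3 = 4.0 / 3.0 * math.pi * ((outer_nm * 1e-7) ** 3 - (inner * 1e-7) ** 3)
        mass_g += vol_cm3 * mat.density
        inner = outer_nm
    return mass_g * 1e3  # g -> mg


def cell_volume_ml(cell_radius_um: float = const.CELL_RADIUS_UM) -> float:
    """Whole-cell sphere volume in mL (the concentration reference volume)."""
    return 4.0 / 3.0 * math.pi * (cell_radius_um * 1e-4) ** 3


def np_count_from_concentration(
    concentration_mg_ml: float,
    reference_volume_ml: float,
    np_model: NanoparticleModel,
) -> int:
    """Number of nanoparticles holding `concentration` in `reference_volume`.

    Nearest-integer rounding; reference volume is the whole-cell sphere by
    convention (reproduces the published table exactly).
    """
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be non-negative")
    return int(round(concentration_mg_ml * reference_volume_ml / np_mass(np_model)))


@dataclass
class CellModel:
    """Water cell with a concentric water nucleus and nanoparticles in the cytoplasm."""

    cell_radius_um: float = const.CELL_RADIUS_UM
    nucleus_radius_um: float = const.NUCLEUS_RADIUS_UM
    np_model: NanoparticleModel = field(default_factory=core_shell_np)
    np_positions_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        if not 0 <= self.nucleus_radius_um <= self.cell_radius_um:
            raise InvalidGeometryError("nucleus must fit inside the cell")

    @property
    def cytoplasm_volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.cell_radius_um**3 - self.nucleus_radius_um**3)


def place_nanoparticles(
    n: int,
    cell: CellModel,
    seed: int,
    max_attempts_per_np: int = 2000,
) -> np.ndarray:
    """Uniform non-overlapping nanoparticle centres in the cytoplasm.

    Rejection sampling in the spherical shell
    [nucleus_radius + r_np, cell_radius - r_np]; pairwise centre distance
    >= 2 r_np.  Deterministic for a fixed seed.  Returns (n, 3) positions in um.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.zeros((0, 3))
    rng = np.random.default_rng(seed)
    r_np = cell.np_model.radius_nm * 1e-3  # um
    r_lo = cell.nucleus_radius_um + r_np
    r_hi = cell.cell_radius_um - r_np
    if r_hi <= r_lo:
        raise PlacementError(
            f"no feasible region: shell [{r_lo}, {r_hi}] um is empty"
        )
    min_d2 = (2.0 * r_np) ** 2
    positions = np.empty((n, 3))
    # coarse grid for neighbour lookup keeps placement O(n)
    cell_size = max(2.0 * r_np, 1e-6)
    grid: dict[tuple, list] = {}

    def grid_key(p):
        return (int(p[0] // cell_size), int(p[1] // cell_size), int(p[2] // cell_size))

    placed = 0
    attempts = 0
    budget = max_attempts_per_np * n
    while placed < n:
        if attempts >= budget:
            raise PlacementError(
                f"placement budget exhausted: placed {placed}/{n} after {attempts} draws"
            )
        attempts += 1
        p = rng.uniform(-r_hi, r_hi, size=3)
        r = math.sqrt(p @ p)
        if not (r_lo <= r <= r_hi):
            continue
        key = grid_key(p)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = positions[j] - p
                        if d @ d < min_d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        positions[placed] = p
        grid.setdefault(key, []).append(placed)
        placed += 1
    return positions


# region labels
REGION_WORLD = "world-water"
REGION_CYTOPLASM = "cytoplasm"
REGION_NUCLEUS = "nucleus"


@dataclass
class WorldGeometry:
    """Total region map for a simulation world.

    Two shapes are used: a single nanoparticle at the origin inside a water
    world (sphere of `world_radius_nm`, or a cube of half-size
    `box_half_nm`), and a cell world (nucleus/cell spheres at the origin,
    nanoparticles at `np_positions_um`, water world sphere).
    Boundary points resolve to the inner region (half-open convention).
    """

    np_model: NanoparticleModel | None = None
    world_radius_nm: float = const.SINGLE_NP_WORLD_RADIUS_UM * 1e3
    box_half_nm: float | None = None
    cell: CellModel | None = None

    def locate(self, point_nm) -> str:
        """Region label at a point (nm).  Every point resolves to exactly one region."""
        p = np.asarray(point_nm, dtype=float)
        if self.cell is not None:
            # nanoparticle layers take precedence over cytoplasm
            pos_nm = self.cell.np_positions_um * 1e3
            if len(pos_nm):
                d2 = ((pos_nm - p) ** 2).sum(axis=1)
                j = int(np.argmin(d2))
                r_local = math.sqrt(d2[j])
                if r_local <= self.cell.np_model.radius_nm:
                    return f"np-{self.cell.np_model.material_at(r_local).name}"
            r = math.sqrt(p @ p)
            if r <= self.cell.nucleus_radius_um * 1e3:
                return REGION_NUCLEUS
            if r <= self.cell.cell_radius_um * 1e3:
                return REGION_CYTOPLASM
            return REGION_WORLD
        r = math.sqrt(p @ p)
        if self.np_model is not None and r <= self.np_model.radius_nm:
            return f"np-{self.np_model.material_at(r).name}"
        return REGION_WORLD

    def inside_world(self, point_nm) -> bool:
        p = np.asarray(point_nm, dtype=float)
        if self.box_half_nm is not None:
            return bool(np.all(np.abs(p) <= self.box_half_nm))
        return float(p @ p) <= self.world_radius_nm**2


def locate(point_nm, world: WorldGeometry) -> str:
    """Functional form of WorldGeometry.locate."""
    return world.locate(point_nm)
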