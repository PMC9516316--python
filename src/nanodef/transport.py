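"""Reference Monte-Carlo transport engine.

Photon free flight with region-resolved exponential path sampling, the
photoelectric and Compton channels, single-generation atomic relaxation, and
condensed-history electron transport (continuous slowing down per substep,
Gaussian multiple-scattering kicks, optional uniform magnetic deflection).

This module is the readable per-particle implementation of the transport
contracts; the pipelines run the same physics through the compiled kernels in
``_kernels``.  Both are cross-checked in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as const
from .materials import GOLD, MAGNETITE, WATER, Material, WorldGeometry
from .physics.compton import klein_nishina_sample
from .physics.relaxation import relax_vacancy
from .physics.stopping import StoppingPowerModel, water_stopping_model
from .physics.tables import ELEMENT_EDGES_KEV, CrossSectionSet, mu_pe_element

# radiation lengths, g/cm^2 (for the Highland multiple-scattering width)
RADIATION_LENGTH = {"water": 36.08, "gold": 6.46, "magnetite": 16.57}

_REGION_MATERIAL = {"np-gold": GOLD, "np-magnetite": MAGNETITE}


def region_material(label: str) -> Material:
    return _REGION_MATERIAL.get(label, WATER)


@dataclass
class ParticleState:
    kind: str                    # "photon" | "electron"
    position_nm: np.ndarray
    direction: np.ndarray
    energy_kev: float
    weight: float = 1.0
    alive: bool = True
    birth_region: str = ""

    def __post_init__(self):
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = math.sqrt(self.direction @ self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("zero direction")
            self.direction = self.direction / norm
        if self.energy_kev < 0:
            raise ValueError("negative energy")
        if self.weight <= 0:
            raise ValueError("non-positive weight")


@dataclass(frozen=True)
class MagneticFieldSpec:
    magnitude_tesla: float = 0.0
    direction: tuple = (1.0, 0.0, 0.0)  # perpendicular to the +z beam by default

    def __post_init__(self):
        if self.magnitude_tesla < 0:
            raise ValueError("B must be non-negative")
        d = np.asarray(self.direction, dtype=float)
        n = math.sqrt(d @ d)
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", tuple(d / n))


@dataclass(frozen=True)
class TransportConfig:
    cutoff_kev: float = 1.0
    substep_fraction: float = 0.05
    auger: bool = True
    seed: int = 0
    histories: int = 1000
    force_interaction: bool = False   # variance reduction, off by default
    max_secondaries: int = 1_000_000

    def __post_init__(self):
        if self.cutoff_kev < 0.1:
            raise ValueError("cutoff must be >= 100 eV")
        if not 0.0 < self.substep_fraction <= 0.2:
            raise ValueError("substep fraction must lie in (0, 0.2]")


@dataclass
class InteractionEvent:
    site_nm: np.ndarray
    type: str                    # "photoelectric" | "compton"
    primary_energy_kev: float
    secondaries: list
    local_deposit_kev: float
    weight: float = 1.0


def gyroradius_mm(energy_kev: float, b_tesla: float) -> float:
    """Relativistic electron gyroradius r = p/(qB) in mm."""
    if b_tesla <= 0:
        return math.inf
    pc_kev = math.sqrt(energy_kev**2 + 2.0 * energy_kev * const.ELECTRON_REST_KEV)
    return pc_kev * 1e3 / (const.SPEED_OF_LIGHT_M_S * b_tesla) * 1e3


# ---------------------------------------------------------------------------
# geometry marching

_EPS_NM = 1e-6


def _sphere_exit(p, d, radius, center=None):
    """Smallest t > eps with |p + t d - c| = radius, else inf."""
    if center is not None:
        p = p - center
    b = p @ d
    c = p @ p - radius * radius
    disc = b * b - c
    if disc <= 0:
        return math.inf
    sq = math.sqrt(disc)
    for t in (-b - sq, -b + sq):
        if t > _EPS_NM:
            return t
    return math.inf


def distance_to_boundary(world: WorldGeometry, p, d) -> float:
    """Distance (nm) to the nearest region boundary or world surface along d."""
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    ts = []
    if world.cell is not None:
        for r_um in (world.cell.nucleus_radius_um, world.cell.cell_radius_um):
            ts.append(_sphere_exit(p, d, r_um * 1e3))
        r_np = world.cell.np_model.radius_nm
        for centre in np.atleast_2d(world.cell.np_positions_um) * 1e3:
            if len(centre) == 0:
                continue
            ts.append(_sphere_exit(p, d, r_np, centre))
            # inner layer boundaries of the nanoparticle
            for outer_nm, _ in world.cell.np_model.layers[:-1]:
                ts.append(_sphere_exit(p, d, outer_nm, centre))
    elif world.np_model is not None:
        for outer_nm, _ in world.np_model.layers:
            ts.append(_sphere_exit(p, d, outer_nm))
    if world.box_half_nm is not None:
        h = world.box_half_nm
        for axis in range(3):
            if d[axis] > 0:
                ts.append((h - p[axis]) / d[axis])
            elif d[axis] < 0:
                ts.append((-h - p[axis]) / d[axis])
    else:
        ts.append(_sphere_exit(p, d, world.world_radius_nm))
    ts = [t for t in ts if t > _EPS_NM]
    return min(ts) if ts else math.inf


# ---------------------------------------------------------------------------
# photon transport

def _segments(world: WorldGeometry, p, d):
    """Yield (entry point, length nm, material) segments until world exit."""
    pos = np.asarray(p, dtype=float).copy()
    d = np.asarray(d, dtype=float)
    while world.inside_world(pos):
        t = distance_to_boundary(world, pos, d)
        if not math.isfinite(t):
            return
        mid = pos + 0.5 * t * d
        yield pos.copy(), t, region_material(world.locate(mid))
        pos = pos + (t + _EPS_NM) * d


def ray_optical_depth(world: WorldGeometry, p, d, energy_kev: float) -> float:
    """Total optical depth along the ray to world exit."""
    tau = 0.0
    for _, length_nm, mat in _segments(world, p, d):
        mu_lin = CrossSectionSet(mat).mu_linear(energy_kev)  # 1/cm
        tau += mu_lin * length_nm * 1e-7
    return tau


def photon_step(
    state: ParticleState,
    world: WorldGeometry,
    rng: np.random.Generator,
    forced: bool = False,
):
    """Free flight to the next interaction; returns an InteractionEvent or None.

    The free path is sampled from the exponential with the region-resolved
    linear attenuation, re-sampled across boundaries via cumulative optical
    depth.  With ``forced`` the interaction is forced to occur before world
    exit and the event carries weight ``w * (1 - exp(-tau_total))``.
    """
    E = state.energy_kev
    if forced:
        tau_total = ray_optical_depth(world, state.position_nm, state.direction, E)
        if tau_total <= 0:
            state.alive = False
            return None
        u = -math.log1p(-rng.random() * (1.0 - math.exp(-tau_total)))
        weight_factor = 1.0 - math.exp(-tau_total)
    else:
        u = -math.log(max(rng.random(), 1e-300))
        weight_factor = 1.0
    remaining = u
    for start, length_nm, mat in _segments(world, state.position_nm, state.direction):
        xs = CrossSectionSet(mat)
        mu_lin = xs.mu_linear(E)  # 1/cm
        tau_seg = mu_lin * length_nm * 1e-7
        if tau_seg < remaining:
            remaining -= tau_seg
            continue
        t_nm = remaining / (mu_lin * 1e-7) if mu_lin > 0 else 0.0
        site = start + t_nm * state.direction
        state.alive = False
        pe = xs.mu(E, "photoelectric")
        tot = pe + xs.mu(E, "compton")
        if rng.random() * tot < pe:
            event = photoelectric_event(E, mat, rng, site=site, rng_direction=True)
        else:
            event = _compton_event(state, mat, site, rng)
        event.weight = state.weight * weight_factor
        return event
    state.alive = False
    return None  # escape


def _isotropic(rng):
    cos_t = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(1.0 - cos_t * cos_t)
    return np.array([s * math.cos(phi), s * math.sin(phi), cos_t])


def _rotate_about(d, reference, theta, phi):
    """Direction at polar angle theta, azimuth phi about `reference`."""
    ref = reference / math.sqrt(reference @ reference)
    if abs(ref[2]) < 0.99:
        perp = np.cross(ref, [0.0, 0.0, 1.0])
    else:
        perp = np.cross(ref, [1.0, 0.0, 0.0])
    perp /= math.sqrt(perp @ perp)
    perp2 = np.cross(ref, perp)
    st = math.sin(theta)
    out = math.cos(theta) * ref + st * (math.cos(phi) * perp + math.sin(phi) * perp2)
    return out / math.sqrt(out @ out)


def photoelectric_event(
    energy_kev: float,
    material: Material,
    rng: np.random.Generator,
    site=None,
    auger: bool = True,
    rng_direction: bool = True,
) -> InteractionEvent:
    """Photoelectric absorption in `material`.

    The absorbing element is sampled proportionally to its mass-fraction
    weighted photoelectric coefficient; the deepest accessible shell is
    ionized; the photoelectron (isotropic direction) carries E - binding and
    the vacancy relaxes.  Energy is conserved exactly.  If the photon energy
    is below every edge the event degenerates to a local deposit.
    """
    site = np.zeros(3) if site is None else np.asarray(site, dtype=float)
    weights = []
    for sym, frac in material.composition:
        weights.append(frac * mu_pe_element(sym, energy_kev))
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    element = material.composition[-1][0]
    for (sym, _), w in zip(material.composition, weights):
        acc += w
        if u <= acc:
            element = sym
            break
    edges = ELEMENT_EDGES_KEV[element]
    accessible = [(b, s) for s, b in edges.items() if b < energy_kev]
    if not accessible:
        return InteractionEvent(site, "photoelectric", energy_kev, [], energy_kev)
    binding, shell = max(accessible)
    secondaries = []
    direction = _isotropic(rng) if rng_direction else np.array([0.0, 0.0, 1.0])
    secondaries.append(
        ParticleState("electron", site, direction, energy_kev - binding, birth_region="")
    )
    outcome = relax_vacancy(element, shell, rng, auger_enabled=auger)
    for q in outcome.quanta:
        secondaries.append(
            ParticleState(q.kind, site, _isotropic(rng), q.energy_kev)
        )
    return InteractionEvent(site, "photoelectric", energy_kev, secondaries, outcome.local_deposit_kev)


def _compton_event(state, material, site, rng) -> InteractionEvent:
    E = state.energy_kev
    e_sc, theta = klein_nishina_sample(E, rng)
    phi = 2.0 * math.pi * rng.random()
    d_sc = _rotate_about(None, state.direction, theta, phi)
    # electron direction from momentum conservation, exact
    p_e = E * state.direction - e_sc * d_sc
    t_e = E - e_sc
    secondaries = [ParticleState("photon", site, d_sc, e_sc)]
    if t_e > 0:
        norm = math.sqrt(p_e @ p_e)
        secondaries.append(ParticleState("electron", site, p_e / norm, t_e))
    return InteractionEvent(site, "compton", E, secondaries, 0.0)


# ---------------------------------------------------------------------------
# electron transport

_STOPPING_CACHE: dict = {}


def stopping_model(material: Material) -> StoppingPowerModel:
    if material.name == "water":
        return water_stopping_model()
    if material.name not in _STOPPING_CACHE:
        _STOPPING_CACHE[material.name] = StoppingPowerModel(material)
    return _STOPPING_CACHE[material.name]


def highland_theta0(material: Material, energy_kev: float, step_nm: float) -> float:
    """Gaussian multiple-scattering width for one substep (rad), capped.

    The pure sqrt(x/X0) Highland form without the thick-step logarithmic
    correction: at nanometre substeps the correction is outside its validity
    and would make the accumulated angular diffusion depend on step size.
    """
    x_g_cm2 = step_nm * 1e-7 * material.density
    x0 = RADIATION_LENGTH[material.name]
    frac = x_g_cm2 / x0
    if frac <= 0:
        return 0.0
    pc = math.sqrt(energy_kev**2 + 2.0 * energy_kev * const.ELECTRON_REST_KEV)
    beta_pc_mev = (pc * pc / (energy_kev + const.ELECTRON_REST_KEV)) * 1e-3
    theta = 13.6 / beta_pc_mev * math.sqrt(frac)
    return min(max(theta, 0.0), 1.0)


def electron_step(
    state: ParticleState,
    world: WorldGeometry,
    rng: np.random.Generator,
    config: TransportConfig,
    b_field: MagneticFieldSpec | None = None,
    scatter: bool = True,
    max_step_nm: float = math.inf,
):
    """One condensed-history substep; returns (deposit site, deposited keV).

    Substep length is bounded by the substep fraction of the residual range,
    the distance to the next region boundary and ``max_step_nm`` (the caller
    passes the local scoring-shell width).  Below the cutoff the remaining
    energy deposits locally and the electron dies.
    """
    E = state.energy_kev
    if E <= config.cutoff_kev:
        state.alive = False
        site = state.position_nm.copy()
        state.energy_kev = 0.0
        return site, E
    mat = region_material(world.locate(state.position_nm + _EPS_NM * state.direction))
    sp = stopping_model(mat)
    range_nm = sp.csda_range_um(min(E, 1000.0)) * 1e3
    t_boundary = distance_to_boundary(world, state.position_nm, state.direction)
    s = min(config.substep_fraction * range_nm, t_boundary + _EPS_NM, max_step_nm)
    s = max(s, 1e-3)  # never stall
    r_res = np.interp(E, sp.energy_kev, sp.range_g_cm2)
    r_new = r_res - s * 1e-7 * mat.density
    if r_new <= sp.range_g_cm2[0]:
        e_new = 0.0
    else:
        e_new = float(np.exp(np.interp(np.log(r_new), sp._log_r, sp._log_e)))
        if e_new <= config.cutoff_kev:
            e_new = 0.0
    deposit = E - e_new
    mid = state.position_nm + 0.5 * s * state.direction
    state.position_nm = state.position_nm + s * state.direction
    state.energy_kev = e_new
    if e_new <= 0.0:
        state.alive = False
    if not world.inside_world(state.position_nm):
        state.alive = False
    # angular deflections
    if state.alive:
        if scatter:
            theta0 = highland_theta0(mat, E, s)
            if theta0 > 0:
                gx = rng.normal(0.0, theta0)
                gy = rng.normal(0.0, theta0)
                theta = math.hypot(gx, gy)
                phi = 2.0 * math.pi * rng.random()
                state.direction = _rotate_about(None, state.direction, min(theta, math.pi / 2), phi)
        if b_field is not None and b_field.magnitude_tesla > 0:
            r_g_nm = gyroradius_mm(max(E, config.cutoff_kev), b_field.magnitude_tesla) * 1e6
            phi_rot = -s / r_g_nm  # negative charge
            b_hat = np.asarray(b_field.direction)
            d = state.direction
            d_par = (d @ b_hat) * b_hat
            d_perp = d - d_par
            norm_perp = math.sqrt(d_perp @ d_perp)
            if norm_perp > 1e-12:
                e1 = d_perp / norm_perp
                e2 = np.cross(b_hat, e1)
                d_perp_new = norm_perp * (math.cos(phi_rot) * e1 + math.sin(phi_rot) * e2)
                new_d = d_par + d_perp_new
                state.direction = new_d / math.sqrt(new_d @ new_d)
    return mid, deposit


@dataclass
class HistoryResult:
    deposited_kev: float = 0.0
    escaped_kev: float = 0.0
    deposits: list = field(default_factory=list)  # (site, keV, region)
    interactions: list = field(default_factory=list)

    @property
    def total_kev(self) -> float:
        return self.deposited_kev + self.escaped_kev


def run_history(
    primary: ParticleState,
    world: WorldGeometry,
    config: TransportConfig,
    rng: np.random.Generator,
    b_field: MagneticFieldSpec | None = None,
    scorer=None,
    record_deposits: bool = True,
) -> HistoryResult:
    """Transport one primary and all its secondaries to completion.

    Energy balance holds per history: primary energy (times weight) equals
    deposits plus escapes to within floating-point round-off.
    """
    result = HistoryResult()
    stack = [primary]
    n_secondary = 0

    def deposit(site, e_kev, weight):
        if e_kev <= 0:
            return
        result.deposited_kev += e_kev * weight
        if record_deposits:
            result.deposits.append((np.asarray(site, dtype=float), e_kev * weight, world.locate(site)))
        if scorer is not None:
            scorer.add(site, e_kev, weight)

    while stack:
        p = stack.pop()  # LIFO
        if p.kind == "photon":
            if p.energy_kev < const.ENERGY_GRID_MIN_KEV:
                deposit(p.position_nm, p.energy_kev, p.weight)
                continue
            forced = config.force_interaction and not p.birth_region
            event = photon_step(p, world, rng, forced=forced)
            if event is None:
                result.escaped_kev += p.energy_kev * p.weight
                continue
            w = event.weight
            if forced:
                result.escaped_kev += p.energy_kev * (p.weight - w)
            result.interactions.append(event)
            deposit(event.site_nm, event.local_deposit_kev, w)
            for sec in event.secondaries:
                sec.weight = w
                sec.birth_region = world.locate(event.site_nm)
                n_secondary += 1
                if n_secondary > config.max_secondaries:
                    raise RuntimeError("secondary stack overflow guard tripped")
                stack.append(sec)
        else:
            while p.alive:
                site, e_dep = electron_step(p, world, rng, config, b_field=b_field)
                deposit(site, e_dep, p.weight)
            if not world.inside_world(p.position_nm) and p.energy_kev > 0:
                result.escaped_kev += p.energy_kev * p.weight
    return result
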