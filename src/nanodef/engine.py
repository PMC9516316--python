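"""Array-level bridge between the object model and the compiled kernels.

Builds the physics "pack" (cross-section, range and relaxation arrays shared
by every kernel), converts geometry objects to plain arrays, and exposes the
three production runs: single-nanoparticle histories (one-step scoring or
step-1 surface recording), step-2 phase-space replay, and the cell model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as const
from . import _kernels as K
from .materials import GOLD, MAGNETITE, WATER, CellModel, NanoparticleModel
from .physics.stopping import StoppingPowerModel
from .physics.tables import ELEMENT_EDGES_KEV, element_pe_grid, mu_pe_element
from .scoring import RadialShellGrid, RegionDoseTally, ShellDoseProfile
from .sources import EnergySpectrum, PhaseSpace, delta_spectrum
from .transport import RADIATION_LENGTH

MAT_IDS = {"water": 0, "gold": 1, "magnetite": 2}
_MATERIALS = [WATER, GOLD, MAGNETITE]
EL_IDS = {"H": 0, "O": 1, "Fe": 2, "Au": 3}
_ELEMENTS = ["H", "O", "Fe", "Au"]

_PACK = None


def build_pack():
    """Physics arrays for the kernels (built once per process)."""
    global _PACK
    if _PACK is not None:
        return _PACK
    n_mat, n_el = len(_MATERIALS), len(_ELEMENTS)
    # per-element photoelectric tables
    el_grids = [element_pe_grid(sym) for sym in _ELEMENTS]
    k_el = max(len(e) for e, _ in el_grids)
    el_loge = np.zeros((n_el, k_el))
    el_logv = np.zeros((n_el, k_el))
    el_len = np.zeros(n_el, dtype=np.int64)
    for i, (e, v) in enumerate(el_grids):
        el_loge[i, : len(e)] = np.log(e)
        el_logv[i, : len(e)] = np.log(v)
        el_loge[i, len(e):] = np.log(e[-1]) + np.arange(1, k_el - len(e) + 1)
        el_logv[i, len(e):] = np.log(v[-1])
        el_len[i] = len(e)
    # per-material photoelectric tables on the union grid of constituents
    mat_tables = []
    for mat in _MATERIALS:
        nodes = np.unique(np.concatenate([element_pe_grid(s)[0] for s, _ in mat.composition]))
        vals = np.zeros_like(nodes)
        for sym, frac in mat.composition:
            vals += frac * mu_pe_element(sym, nodes)
        mat_tables.append((nodes, vals))
    k_mat = max(len(n) for n, _ in mat_tables)
    pe_loge = np.zeros((n_mat, k_mat))
    pe_logv = np.zeros((n_mat, k_mat))
    pe_len = np.zeros(n_mat, dtype=np.int64)
    for i, (e, v) in enumerate(mat_tables):
        pe_loge[i, : len(e)] = np.log(e)
        pe_logv[i, : len(e)] = np.log(v)
        pe_loge[i, len(e):] = np.log(e[-1]) + np.arange(1, k_mat - len(e) + 1)
        pe_logv[i, len(e):] = np.log(v[-1])
        pe_len[i] = len(e)
    mat_el_id = np.full((n_mat, 2), -1, dtype=np.int64)
    mat_el_frac = np.zeros((n_mat, 2))
    for i, mat in enumerate(_MATERIALS):
        for j, (sym, frac) in enumerate(mat.composition):
            mat_el_id[i, j] = EL_IDS[sym]
            mat_el_frac[i, j] = frac
    epg = np.array([m.electrons_per_gram for m in _MATERIALS])
    rho = np.array([m.density for m in _MATERIALS])
    # range tables on a common energy grid
    sp_models = [StoppingPowerModel(m) for m in _MATERIALS]
    sp_loge = np.log(sp_models[0].energy_kev)
    sp_logr = np.stack([np.log(sm.range_g_cm2) for sm in sp_models])
    x0 = np.array([RADIATION_LENGTH[m.name] for m in _MATERIALS])
    bind = np.zeros((n_el, 3))
    fy = np.zeros((n_el, 2))
    from .physics.relaxation import FLUORESCENCE_YIELD

    for i, sym in enumerate(_ELEMENTS):
        edges = ELEMENT_EDGES_KEV[sym]
        for j, shell in enumerate(("K", "L", "M")):
            bind[i, j] = edges.get(shell, 0.0)
        fyd = FLUORESCENCE_YIELD[sym]
        fy[i, 0] = fyd.get("K", 0.0)
        fy[i, 1] = fyd.get("L", 0.0)
    _PACK = (
        pe_loge, pe_logv, pe_len, el_loge, el_logv, el_len,
        mat_el_id, mat_el_frac, epg, rho, sp_loge, sp_logr, x0, bind, fy,
    )
    return _PACK


def _np_arrays(np_model: NanoparticleModel):
    radii = np.array([r for r, _ in np_model.layers])
    mats = np.array([MAT_IDS[m.name] for _, m in np_model.layers], dtype=np.int64)
    return radii, mats


def _spectrum_arrays(source):
    if isinstance(source, (int, float)):
        source = delta_spectrum(float(source))
    if not isinstance(source, EnergySpectrum):
        raise TypeError("source must be an energy (keV) or an EnergySpectrum")
    cdf = np.concatenate([[0.0], np.cumsum(source.weights)])
    cdf[-1] = 1.0
    return source.edges_kev.astype(float), cdf


def _bfield_arrays(b_field):
    if b_field is None:
        return 0.0, 1.0, 0.0, 0.0
    return (float(b_field.magnitude_tesla),) + tuple(float(c) for c in b_field.direction)


@dataclass
class SingleNPResult:
    profile: ShellDoseProfile
    phase_space: PhaseSpace | None
    escaped_kev: float
    source_kev: float
    deposited_kev: float
    n_photoelectric: int
    n_compton: int
    n_histories: int


def run_single_np(
    np_model: NanoparticleModel,
    source,
    n_histories: int,
    seed: int,
    beam_radius_nm: float = const.NP_RADIUS_NM,
    world: str = "sphere",           # "sphere" (20 um scoring world) | "box" (step-1 box)
    force_mode: int = 1,             # 0 analog, 1 forced whole-ray, 2 forced NP chord
    record_surface: bool = False,
    b_field=None,
    cutoff_kev: float = 1.0,
    substep_fraction: float = 0.05,
    auger: bool = True,
    scatter: bool = True,
    max_records: int = 6_000_000,
    fine_scoring: bool = True,
    label: str = "",
) -> SingleNPResult:
    """Photon beam on a single nanoparticle at the origin.

    ``fine_scoring=False`` replaces the radial shell grid by a single coarse
    shell; surface-recording (step 1) runs use it since only the phase space
    matters there and the 1 nm substep caps of the fine grid dominate cost.
    """
    pack = build_pack()
    radii, mats = _np_arrays(np_model)
    edges, cdf = _spectrum_arrays(source)
    if fine_scoring:
        grid = RadialShellGrid(surface_radius_nm=np_model.radius_nm)
    else:
        grid = RadialShellGrid(surface_radius_nm=np_model.radius_nm,
                               edges_nm=np.array([0.0, 1.0e4]))
    shell_edges = grid.edges_nm
    widths = grid.widths_nm()
    int_mask = ((shell_edges[:-1] >= 1.0) & (shell_edges[1:] <= 9950.0)).astype(np.int64)
    nstot = grid.n_shells + 3
    sums = np.zeros(nstot)
    sums2 = np.zeros(nstot)
    use_box = 1 if world == "box" else 0
    box_h = const.STEP1_BOX_HALF_NM if use_box else 0.0
    world_r = const.SINGLE_NP_WORLD_RADIUS_UM * 1e3
    n_rec_cap = max_records if record_surface else 1
    rec = [np.zeros(n_rec_cap) for _ in range(8)]
    rec_hist = np.zeros(n_rec_cap, dtype=np.int64)
    b_mag, bdx, bdy, bdz = _bfield_arrays(b_field)
    n_rec, escaped, src, dep, n_pe, n_co = K.run_single_np(
        pack, seed, n_histories, edges, cdf, beam_radius_nm, -np_model.radius_nm,
        radii, mats, len(radii), MAT_IDS["water"], world_r, box_h, use_box,
        b_mag, bdx, bdy, bdz, cutoff_kev, substep_fraction,
        1 if auger else 0, 1 if scatter else 0, force_mode,
        shell_edges, widths, int_mask, np_model.radius_nm,
        1 if record_surface else 0, rec[0], rec[1], rec[2], rec[3], rec[4], rec[5],
        rec[6], rec[7], rec_hist, sums, sums2,
    )
    if record_surface and n_rec >= n_rec_cap:
        raise RuntimeError("phase-space record buffer overflow; raise max_records")
    profile = ShellDoseProfile.from_arrays(
        grid, sums[: grid.n_shells], sums2[: grid.n_shells], n_histories,
        np_internal_kev=sums[grid.n_shells],
        int_sum_kev=sums[grid.n_shells + 2], int_sum_kev2=sums2[grid.n_shells + 2],
        label=label or np_model.label,
    )
    phsp = None
    if record_surface:
        phsp = PhaseSpace(
            position_nm=np.stack([rec[0][:n_rec], rec[1][:n_rec], rec[2][:n_rec]], axis=1),
            direction=np.stack([rec[3][:n_rec], rec[4][:n_rec], rec[5][:n_rec]], axis=1),
            energy_kev=rec[6][:n_rec],
            kind=np.ones(n_rec, dtype=int),
            weight=rec[7][:n_rec],
            history=rec_hist[:n_rec],
            header={
                "format": "nanodef-phsp-1",
                "np_model": np_model.label,
                "source": getattr(source, "label", f"{source} keV"),
                "seed": seed,
                "history_count": n_histories,
            },
        )
    return SingleNPResult(profile, phsp, escaped, src, dep, n_pe, n_co, n_histories)


def run_step2(
    phase_space: PhaseSpace,
    seed: int,
    surface_radius_nm: float = const.NP_RADIUS_NM,
    b_field=None,
    cutoff_kev: float = 1.0,
    substep_fraction: float = 0.05,
    scatter: bool = True,
    label: str = "",
) -> SingleNPResult:
    """Replay surface electrons from the centre of the 20 um water sphere."""
    pack = build_pack()
    grid = RadialShellGrid(surface_radius_nm=surface_radius_nm)
    shell_edges = grid.edges_nm
    widths = grid.widths_nm()
    int_mask = ((shell_edges[:-1] >= 1.0) & (shell_edges[1:] <= 9950.0)).astype(np.int64)
    nstot = grid.n_shells + 3
    sums = np.zeros(nstot)
    sums2 = np.zeros(nstot)
    sel = phase_space.kind == 1
    order = np.argsort(phase_space.history[sel], kind="stable")
    pos = phase_space.position_nm[sel][order]
    d = phase_space.direction[sel][order]
    e = phase_space.energy_kev[sel][order]
    w = phase_space.weight[sel][order]
    hist = phase_space.history[sel][order].astype(np.int64)
    n_src = max(phase_space.n_source, int(hist.max()) + 1 if len(hist) else 1)
    b_mag, bdx, bdy, bdz = _bfield_arrays(b_field)
    escaped, src, dep = K.run_step2(
        pack, seed, n_src,
        np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
        np.ascontiguousarray(pos[:, 2]),
        np.ascontiguousarray(d[:, 0]), np.ascontiguousarray(d[:, 1]),
        np.ascontiguousarray(d[:, 2]),
        e.astype(float), w.astype(float), hist,
        const.SINGLE_NP_WORLD_RADIUS_UM * 1e3,
        b_mag, bdx, bdy, bdz, cutoff_kev, substep_fraction, 1 if scatter else 0,
        shell_edges, widths, int_mask, surface_radius_nm,
        sums, sums2,
    )
    profile = ShellDoseProfile.from_arrays(
        grid, sums[: grid.n_shells], sums2[: grid.n_shells], n_src,
        np_internal_kev=sums[grid.n_shells],
        int_sum_kev=sums[grid.n_shells + 2], int_sum_kev2=sums2[grid.n_shells + 2],
        label=label or phase_space.header.get("np_model", ""),
    )
    return SingleNPResult(profile, None, escaped, src, dep, 0, 0, n_src)


def _np_grid_csr(positions_nm: np.ndarray, r_np_nm: float, r_cell_nm: float):
    """xy-bucket CSR lookup of nanoparticles for primary rays along +z."""
    cell = max(4.0 * r_np_nm, 200.0)
    x0 = y0 = -(r_cell_nm + 2.0 * r_np_nm)
    nx = ny = int(math.ceil(2.0 * (r_cell_nm + 2.0 * r_np_nm) / cell))
    buckets: dict = {}
    for j, (x, y, _z) in enumerate(positions_nm):
        ix_lo = int((x - r_np_nm - x0) / cell)
        ix_hi = int((x + r_np_nm - x0) / cell)
        iy_lo = int((y - r_np_nm - y0) / cell)
        iy_hi = int((y + r_np_nm - y0) / cell)
        for ix in range(max(ix_lo, 0), min(ix_hi, nx - 1) + 1):
            for iy in range(max(iy_lo, 0), min(iy_hi, ny - 1) + 1):
                buckets.setdefault(ix * ny + iy, []).append(j)
    start = np.zeros(nx * ny + 1, dtype=np.int64)
    items: list = []
    for c in range(nx * ny):
        start[c] = len(items)
        items.extend(buckets.get(c, ()))
    start[nx * ny] = len(items)
    return x0, y0, cell, nx, ny, start, np.array(items, dtype=np.int64)


@dataclass
class CellRunResult:
    tally: RegionDoseTally
    escaped_kev: float
    source_kev: float
    deposited_kev: float
    n_photoelectric: int
    n_compton: int
    n_np_interactions: int
    n_histories: int


def run_cell(
    cell: CellModel,
    source,
    n_histories: int,
    seed: int,
    beam_radius_um: float | None = None,
    b_field=None,
    cutoff_kev: float = 1.0,
    substep_fraction: float = 0.05,
    auger: bool = True,
    scatter: bool = True,
    force: bool = True,
    label: str = "",
) -> CellRunResult:
    """Photon beam of cell diameter on the nanoparticle-loaded cell."""
    pack = build_pack()
    edges, cdf = _spectrum_arrays(source)
    r_cell = cell.cell_radius_um * 1e3
    r_nuc = cell.nucleus_radius_um * 1e3
    beam_r = (beam_radius_um * 1e3) if beam_radius_um else r_cell
    world_r = max(2.0 * r_cell, beam_r + 5.0e3)
    pos_nm = np.asarray(cell.np_positions_um, dtype=float) * 1e3
    n_np = len(pos_nm)
    layers = cell.np_model.layers
    r_np = cell.np_model.radius_nm
    if len(layers) == 2:
        r_core = layers[0][0]
        m_core = MAT_IDS[layers[0][1].name]
        m_shell = MAT_IDS[layers[1][1].name]
    else:
        r_core = 0.0
        m_core = 0
        m_shell = MAT_IDS[layers[0][1].name]
    if n_np:
        gx0, gy0, gcell, gnx, gny, cstart, citems = _np_grid_csr(pos_nm, r_np, r_cell)
        npx, npy, npz = pos_nm[:, 0].copy(), pos_nm[:, 1].copy(), pos_nm[:, 2].copy()
    else:
        gx0 = gy0 = 0.0
        gcell, gnx, gny = 1.0, 1, 1
        cstart = np.zeros(2, dtype=np.int64)
        citems = np.zeros(0, dtype=np.int64)
        npx = npy = npz = np.zeros(0)
    b_mag, bdx, bdy, bdz = _bfield_arrays(b_field)
    sums = np.zeros(5)
    sums2 = np.zeros(5)
    escaped, src, dep, n_pe, n_co, n_np_int = K.run_cell(
        pack, seed, n_histories, edges, cdf, beam_r, -r_cell,
        r_nuc, r_cell, world_r,
        npx, npy, npz, r_np, r_core, m_shell, m_core,
        gx0, gy0, gcell, gnx, gny, cstart, citems,
        b_mag, bdx, bdy, bdz, cutoff_kev, substep_fraction,
        1 if auger else 0, 1 if scatter else 0, 1 if force else 0,
        sums, sums2,
    )
    v_np_um3 = n_np * 4.0 / 3.0 * math.pi * (r_np * 1e-3) ** 3
    tally = RegionDoseTally.from_arrays(
        sums[:2], sums2[:2], n_histories, np_volume_um3=v_np_um3,
        np_internal_kev=sums[2], label=label or cell.np_model.label,
        cell_radius_um=cell.cell_radius_um, nucleus_radius_um=cell.nucleus_radius_um,
    )
    return CellRunResult(tally, escaped, src, dep, n_pe, n_co, n_np_int, n_histories)
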