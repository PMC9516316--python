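"""Compiled Monte-Carlo kernels.

Same physics as ``transport`` (exponential photon flight, photoelectric +
Klein-Nishina Compton channels, single-generation relaxation,
condensed-history electrons with Gaussian multiple scattering and helical
magnetic deflection), written as numba kernels over plain arrays so the
pipelines can run millions of histories.  The physics "pack" tuple is built
by ``engine.build_pack`` from the same tables the reference engine uses.

Conventions: lengths nm, energies keV, attenuation cm^2/g, densities g/cm^3.
Pack layout (tuple indices):
  0 pe_loge[n_mat, K]  1 pe_logv[n_mat, K]  2 pe_len[n_mat]
  3 el_loge[n_el, K]   4 el_logv[n_el, K]   5 el_len[n_el]
  6 mat_el_id[n_mat,2] 7 mat_el_frac[n_mat,2]
  8 epg[n_mat] (electrons/g)  9 rho[n_mat]
 10 sp_loge[Ns] 11 sp_logr[n_mat, Ns] (log range g/cm^2)
 12 x0[n_mat] (radiation length g/cm^2)
 13 bind[n_el, 3] (K, L, M binding keV; 0 = shell absent)
 14 fy[n_el, 2] (K, L fluorescence yields)
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi
MEC2 = 511.0
RE2_2PI = 2.0 * math.pi * 2.8179403262e-13**2  # cm^2
C_M_S = 2.99792458e8
E_FLOOR = 1.0          # photon table floor, keV
EPS_NM = 1e-4
NP_STEP_CAP_NM = 5.0   # fine substep inside nanoparticle layers
STACK = 64


@njit(cache=True)
def _interp(xa, ya, n, x):
    """Linear interpolation with end clamping on xa[:n] increasing."""
    if x <= xa[0]:
        return ya[0]
    if x >= xa[n - 1]:
        return ya[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xa[mid] <= x:
            lo = mid
        else:
            hi = mid
    t = (x - xa[lo]) / (xa[lo + 1] - xa[lo])
    return ya[lo] + t * (ya[lo + 1] - ya[lo])


@njit(cache=True)
def _kn_sigma(e_kev):
    """Klein-Nishina total cross section per electron, cm^2."""
    a = e_kev / MEC2
    t = 1.0 + 2.0 * a
    lt = math.log(t)
    term1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / t - lt / a)
    term2 = lt / (2.0 * a)
    term3 = (1.0 + 3.0 * a) / (t * t)
    return RE2_2PI * (term1 + term2 - term3)


@njit(cache=True)
def _mu_pe(pack, m, e_kev):
    return math.exp(_interp(pack[0][m], pack[1][m], pack[2][m], math.log(e_kev)))


@njit(cache=True)
def _mu_pe_el(pack, el, e_kev):
    return math.exp(_interp(pack[3][el], pack[4][el], pack[5][el], math.log(e_kev)))


@njit(cache=True)
def _mu_compton(pack, m, e_kev):
    return pack[8][m] * _kn_sigma(e_kev)


@njit(cache=True)
def _mu_lin_inv_nm(pack, m, e_kev):
    """Linear attenuation in 1/nm."""
    return pack[9][m] * (_mu_pe(pack, m, e_kev) + _mu_compton(pack, m, e_kev)) * 1e-7


@njit(cache=True)
def _range_gcm2(pack, m, e_kev):
    return math.exp(_interp(pack[10], pack[11][m], len(pack[10]), math.log(e_kev)))


@njit(cache=True)
def _energy_after(pack, m, r_gcm2):
    """Energy whose residual range is r (inverse range table)."""
    logr = pack[11][m]
    n = len(logr)
    lr = math.log(r_gcm2) if r_gcm2 > 0 else -1e30
    if lr <= logr[0]:
        return 0.0
    return math.exp(_interp(logr, pack[10], n, lr))


@njit(cache=True)
def _sample_kn(e_kev):
    """(eps, cos theta) from the Klein-Nishina energy distribution."""
    a = e_kev / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * a)
    bound = eps_min + 1.0 / eps_min
    while True:
        eps = eps_min + (1.0 - eps_min) * np.random.random()
        cost = 1.0 - (1.0 / eps - 1.0) / a
        if cost < -1.0:
            cost = -1.0
        if cost > 1.0:
            cost = 1.0
        f = eps + 1.0 / eps - (1.0 - cost * cost)
        if np.random.random() * bound <= f:
            return eps, cost


@njit(cache=True)
def _rotate(dx, dy, dz, theta, phi):
    """New unit vector at polar angle theta, azimuth phi about (dx,dy,dz)."""
    if abs(dz) < 0.99:
        # perp = d x z
        px, py, pz = dy, -dx, 0.0
    else:
        px, py, pz = 0.0, dz, -dy  # d x x
    n = math.sqrt(px * px + py * py + pz * pz)
    px, py, pz = px / n, py / n, pz / n
    qx = dy * pz - dz * py
    qy = dz * px - dx * pz
    qz = dx * py - dy * px
    st = math.sin(theta)
    ct = math.cos(theta)
    cp = math.cos(phi)
    sp = math.sin(phi)
    ox = ct * dx + st * (cp * px + sp * qx)
    oy = ct * dy + st * (cp * py + sp * qy)
    oz = ct * dz + st * (cp * pz + sp * qz)
    n = math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox / n, oy / n, oz / n


@njit(cache=True)
def _isotropic():
    cost = 2.0 * np.random.random() - 1.0
    phi = TWO_PI * np.random.random()
    s = math.sqrt(1.0 - cost * cost)
    return s * math.cos(phi), s * math.sin(phi), cost


@njit(cache=True)
def _pick_element(pack, m, e_kev):
    ids = pack[6][m]
    fracs = pack[7][m]
    w0 = fracs[0] * _mu_pe_el(pack, ids[0], e_kev) if ids[0] >= 0 else 0.0
    w1 = fracs[1] * _mu_pe_el(pack, ids[1], e_kev) if ids[1] >= 0 else 0.0
    tot = w0 + w1
    if tot <= 0.0:
        return ids[0]
    if np.random.random() * tot < w0:
        return ids[0]
    return ids[1]


@njit(cache=True)
def _deepest_shell(pack, el, e_kev):
    """Deepest accessible shell index (0=K,1=L,2=M) or -1."""
    bind = pack[13][el]
    for s in range(3):
        if bind[s] > 0.0 and bind[s] < e_kev:
            return s
    return -1


@njit(cache=True)
def _relax(pack, el, shell, auger, eq_kind, eq_energy, nq0):
    """Single-generation relaxation; fills emission queue, returns (nq, local deposit).

    eq_kind: 0 photon, 1 electron.
    """
    bind = pack[13][el]
    fy = pack[14][el]
    b = bind[shell]
    if not auger:
        return nq0, b
    nq = nq0
    local = 0.0
    # process a tiny explicit stack of vacancies (shell, count)
    vac_shell = np.empty(8, dtype=np.int64)
    n_vac = 1
    vac_shell[0] = shell
    while n_vac > 0:
        n_vac -= 1
        s = vac_shell[n_vac]
        bs = bind[s]
        if s >= 2 or bind[s + 1] <= 0.0:
            local += bs
            continue
        bl = bind[s + 1]
        if np.random.random() < fy[s]:
            eq_kind[nq] = 0
            eq_energy[nq] = bs - bl
            nq += 1
            vac_shell[n_vac] = s + 1
            n_vac += 1
        else:
            if bs - 2.0 * bl <= 0.0:
                local += bs
                continue
            eq_kind[nq] = 1
            eq_energy[nq] = bs - 2.0 * bl
            nq += 1
            vac_shell[n_vac] = s + 1
            vac_shell[n_vac + 1] = s + 1
            n_vac += 2
        if nq > 48:
            break
    return nq, local


@njit(cache=True)
def _gyro_nm(e_kev, b_tesla):
    pc_kev = math.sqrt(e_kev * e_kev + 2.0 * e_kev * MEC2)
    return pc_kev * 1e3 / (C_M_S * b_tesla) * 1e9  # m -> nm


@njit(cache=True)
def _score(scratch, touched, nt, idx, val):
    if scratch[idx] == 0.0:
        touched[nt] = idx
        nt += 1
    scratch[idx] += val
    return nt


@njit(cache=True)
def _sphere_exit_t(px, py, pz, dx, dy, dz, r):
    b = px * dx + py * dy + pz * dz
    c = px * px + py * py + pz * pz - r * r
    disc = b * b - c
    if disc <= 0.0:
        return 1e30
    sq = math.sqrt(disc)
    t = -b - sq
    if t > EPS_NM:
        return t
    t = -b + sq
    if t > EPS_NM:
        return t
    return 1e30


@njit(cache=True)
def _world_exit_t(px, py, pz, dx, dy, dz, world_r, box_h, use_box):
    if use_box == 1:
        tmin = 1e30
        if dx > 0.0:
            t = (box_h - px) / dx
        elif dx < 0.0:
            t = (-box_h - px) / dx
        else:
            t = 1e30
        if t < tmin:
            tmin = t
        if dy > 0.0:
            t = (box_h - py) / dy
        elif dy < 0.0:
            t = (-box_h - py) / dy
        else:
            t = 1e30
        if t < tmin:
            tmin = t
        if dz > 0.0:
            t = (box_h - pz) / dz
        elif dz < 0.0:
            t = (-box_h - pz) / dz
        else:
            t = 1e30
        if t < tmin:
            tmin = t
        return tmin if tmin > EPS_NM else EPS_NM
    return _sphere_exit_t(px, py, pz, dx, dy, dz, world_r)


@njit(cache=True)
def _inside_world(px, py, pz, world_r, box_h, use_box):
    if use_box == 1:
        return abs(px) <= box_h and abs(py) <= box_h and abs(pz) <= box_h
    return px * px + py * py + pz * pz <= world_r * world_r


@njit(cache=True)
def _layer_at(radii, n_layers, r):
    """Material slot: layer index, or n_layers for outside (water)."""
    for i in range(n_layers):
        if r <= radii[i]:
            return i
    return n_layers


@njit(cache=True)
def _electron_track(
    pack,
    px, py, pz, dx, dy, dz, e0, w,
    # concentric geometry: layer radii/materials around the origin, water beyond
    radii, mats, n_layers, water_mat,
    world_r, box_h, use_box,
    # magnetic field
    b_mag, bdx, bdy, bdz,
    # transport parameters
    cutoff, frac, do_scatter,
    # scoring: mode 0 = radial shells around origin (r0 = shell surface),
    #          1 = cell regions (region_r = [r_nucleus, r_cell]),
    #          2 = nanoparticle-internal only (local birth-NP leg)
    score_mode, shell_edges, shell_widths, int_mask, r0,
    region_r,
    scratch, touched, nt,
    idx_np_internal, idx_other, idx_int,
    # surface recording (mode 0): crossing radius r0, records appended
    record_on, rec_x, rec_y, rec_z, rec_dx, rec_dy, rec_dz, rec_e, rec_w, rec_hist, n_rec, hist_id,
):
    """Transport one electron to rest; returns (nt, n_rec, escaped_kev, exit state...).

    Exit state (x, y, z, dx, dy, dz, E) is meaningful when the electron left
    the world (escaped_kev > 0); used by the birth-NP local leg.
    """
    e = e0
    n_shell = len(shell_edges) - 1
    has_record = 0  # phase-space sources carry each electron once (first crossing)
    while True:
        if e <= cutoff:
            # deposit locally
            r = math.sqrt(px * px + py * py + pz * pz)
            idx = -1
            if score_mode == 0:
                if r < r0:
                    idx = idx_np_internal
                else:
                    d = r - r0
                    if d < shell_edges[n_shell]:
                        k = 0
                        lo = 0
                        hi = n_shell
                        while hi - lo > 1:
                            mid = (lo + hi) // 2
                            if shell_edges[mid] <= d:
                                lo = mid
                            else:
                                hi = mid
                        k = lo
                        nt = _score(scratch, touched, nt, k, e * w)
                        if int_mask[k] == 1:
                            nt = _score(scratch, touched, nt, idx_int, e * w)
                        idx = -2
                    else:
                        idx = idx_other
            elif score_mode == 1:
                if r <= region_r[0]:
                    idx = 1
                elif r <= region_r[1]:
                    idx = 0
                else:
                    idx = idx_other
            else:
                idx = idx_np_internal
            if idx >= 0:
                nt = _score(scratch, touched, nt, idx, e * w)
            return nt, n_rec, 0.0, px, py, pz, dx, dy, dz, 0.0
        r = math.sqrt(px * px + py * py + pz * pz)
        layer = _layer_at(radii, n_layers, r)
        m = mats[layer] if layer < n_layers else water_mat
        rho = pack[9][m]
        r_res = _range_gcm2(pack, m, e)
        s = frac * r_res / rho * 1e7  # nm
        # geometric caps: layer boundaries and world
        t_b = _world_exit_t(px, py, pz, dx, dy, dz, world_r, box_h, use_box)
        for i in range(n_layers):
            t = _sphere_exit_t(px, py, pz, dx, dy, dz, radii[i])
            if t < t_b:
                t_b = t
        # scoring-shell width cap; the scoring surface also acts as a boundary
        if score_mode == 0 and r0 > 0.0:
            t = _sphere_exit_t(px, py, pz, dx, dy, dz, r0)
            if t < t_b:
                t_b = t
        if score_mode == 0 and r >= r0 - 0.01:
            d = r - r0
            if d < 0.0:
                d = 0.0
            if d < shell_edges[n_shell]:
                lo = 0
                hi = n_shell
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if shell_edges[mid] <= d:
                        lo = mid
                    else:
                        hi = mid
                if shell_widths[lo] < s:
                    s = shell_widths[lo]
        if n_layers > 0 and layer < n_layers and NP_STEP_CAP_NM < s:
            s = NP_STEP_CAP_NM
        crossing = False
        if t_b + EPS_NM < s:
            s = t_b + EPS_NM
            crossing = True
        if s < 1e-3:
            s = 1e-3
        r_new = r_res - s * 1e-7 * rho
        e_new = _energy_after(pack, m, r_new)
        if e_new <= cutoff:
            e_new = 0.0
        dep = (e - e_new) * w
        mx = px + 0.5 * s * dx
        my = py + 0.5 * s * dy
        mz = pz + 0.5 * s * dz
        rm = math.sqrt(mx * mx + my * my + mz * mz)
        if score_mode == 0:
            if rm < r0:
                nt = _score(scratch, touched, nt, idx_np_internal, dep)
            else:
                d = rm - r0
                if d < shell_edges[n_shell]:
                    lo = 0
                    hi = n_shell
                    while hi - lo > 1:
                        mid = (lo + hi) // 2
                        if shell_edges[mid] <= d:
                            lo = mid
                        else:
                            hi = mid
                    nt = _score(scratch, touched, nt, lo, dep)
                    if int_mask[lo] == 1:
                        nt = _score(scratch, touched, nt, idx_int, dep)
                else:
                    nt = _score(scratch, touched, nt, idx_other, dep)
        elif score_mode == 1:
            if rm <= region_r[0]:
                nt = _score(scratch, touched, nt, 1, dep)
            elif rm <= region_r[1]:
                nt = _score(scratch, touched, nt, 0, dep)
            else:
                nt = _score(scratch, touched, nt, idx_other, dep)
        else:
            nt = _score(scratch, touched, nt, idx_np_internal, dep)
        r_prev = r
        px += s * dx
        py += s * dy
        pz += s * dz
        e_prev = e
        e = e_new
        # outward surface-crossing record
        if record_on == 1 and has_record == 0:
            r_after = math.sqrt(px * px + py * py + pz * pz)
            if r_prev < r0 and r_after >= r0 and e > 0.0:
                has_record = 1
                if n_rec < len(rec_e):
                    rec_x[n_rec] = px
                    rec_y[n_rec] = py
                    rec_z[n_rec] = pz
                    rec_dx[n_rec] = dx
                    rec_dy[n_rec] = dy
                    rec_dz[n_rec] = dz
                    rec_e[n_rec] = e
                    rec_w[n_rec] = w
                    rec_hist[n_rec] = hist_id
                    n_rec += 1
        if not _inside_world(px, py, pz, world_r, box_h, use_box):
            return nt, n_rec, e * w, px, py, pz, dx, dy, dz, e
        if e <= 0.0:
            return nt, n_rec, 0.0, px, py, pz, dx, dy, dz, 0.0
        # multiple scattering
        if do_scatter == 1:
            x_gcm2 = s * 1e-7 * rho
            x0 = pack[12][m]
            fr = x_gcm2 / x0
            if fr > 0.0:
                pc = math.sqrt(e_prev * e_prev + 2.0 * e_prev * MEC2)
                beta_pc_mev = (pc * pc / (e_prev + MEC2)) * 1e-3
                # pure sqrt(x/X0) Highland width: the thick-step log correction
                # is invalid (and non-additive) at nm-scale substeps
                th0 = 13.6 / beta_pc_mev * math.sqrt(fr)
                if th0 > 1.0:
                    th0 = 1.0
                if th0 > 0.0:
                    gx = np.random.normal() * th0
                    gy = np.random.normal() * th0
                    theta = math.sqrt(gx * gx + gy * gy)
                    if theta > 1.5707963:
                        theta = 1.5707963
                    phi = TWO_PI * np.random.random()
                    dx, dy, dz = _rotate(dx, dy, dz, theta, phi)
        # magnetic deflection (rotate the perpendicular component)
        if b_mag > 0.0:
            rg = _gyro_nm(e if e > cutoff else cutoff, b_mag)
            ang = -s / rg
            dpar = dx * bdx + dy * bdy + dz * bdz
            pxp = dx - dpar * bdx
            pyp = dy - dpar * bdy
            pzp = dz - dpar * bdz
            npn = math.sqrt(pxp * pxp + pyp * pyp + pzp * pzp)
            if npn > 1e-12:
                e1x, e1y, e1z = pxp / npn, pyp / npn, pzp / npn
                e2x = bdy * e1z - bdz * e1y
                e2y = bdz * e1x - bdx * e1z
                e2z = bdx * e1y - bdy * e1x
                ca = math.cos(ang)
                sa = math.sin(ang)
                nx = dpar * bdx + npn * (ca * e1x + sa * e2x)
                ny = dpar * bdy + npn * (ca * e1y + sa * e2y)
                nz = dpar * bdz + npn * (ca * e1z + sa * e2z)
                nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                dx, dy, dz = nx / nn, ny / nn, nz / nn


@njit(cache=True)
def _sample_spec(edges, cdf):
    """Inverse-CDF energy sample, uniform within the chosen bin."""
    u = np.random.random()
    lo = 0
    hi = len(cdf) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cdf[mid] <= u:
            lo = mid
        else:
            hi = mid
    return edges[lo] + (edges[lo + 1] - edges[lo]) * np.random.random()


@njit(cache=True)
def _disk_point(beam_r):
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        if x * x + y * y <= 1.0:
            return x * beam_r, y * beam_r


@njit(cache=True)
def _photon_march_concentric(
    pack, px, py, pz, dx, dy, dz, e_kev,
    radii, mats, n_layers, water_mat, world_r, box_h, use_box, u_target,
):
    """March a photon of optical-depth budget u_target; returns (hit, x, y, z, mat)."""
    u = u_target
    while _inside_world(px, py, pz, world_r, box_h, use_box):
        r = math.sqrt(px * px + py * py + pz * pz)
        layer = _layer_at(radii, n_layers, r)
        m = mats[layer] if layer < n_layers else water_mat
        t_b = _world_exit_t(px, py, pz, dx, dy, dz, world_r, box_h, use_box)
        for i in range(n_layers):
            t = _sphere_exit_t(px, py, pz, dx, dy, dz, radii[i])
            if t < t_b:
                t_b = t
        mu = _mu_lin_inv_nm(pack, m, e_kev)
        tau = mu * t_b
        if tau >= u:
            t_int = u / mu if mu > 0.0 else 0.0
            return 1, px + t_int * dx, py + t_int * dy, pz + t_int * dz, m
        u -= tau
        px += (t_b + EPS_NM) * dx
        py += (t_b + EPS_NM) * dy
        pz += (t_b + EPS_NM) * dz
    return 0, px, py, pz, -1


@njit(cache=True)
def _interact(pack, m, e_kev, dx, dy, dz, auger,
              out_kind, out_e, out_dx, out_dy, out_dz):
    """One photon interaction in material m.

    Fills the secondary queue; returns (n_out, local_deposit, itype) with
    itype 0 = photoelectric, 1 = compton.  Energy is conserved exactly.
    """
    mu_p = _mu_pe(pack, m, e_kev)
    mu_c = _mu_compton(pack, m, e_kev)
    n = 0
    if np.random.random() * (mu_p + mu_c) < mu_p:
        el = _pick_element(pack, m, e_kev)
        shell = _deepest_shell(pack, el, e_kev)
        if shell < 0:
            return 0, e_kev, 0
        binding = pack[13][el][shell]
        ix, iy, iz = _isotropic()
        out_kind[n] = 1
        out_e[n] = e_kev - binding
        out_dx[n] = ix
        out_dy[n] = iy
        out_dz[n] = iz
        n += 1
        nq, local = _relax(pack, el, shell, auger, out_kind, out_e, n)
        for i in range(n, nq):
            ix, iy, iz = _isotropic()
            out_dx[i] = ix
            out_dy[i] = iy
            out_dz[i] = iz
        return nq, local, 0
    eps, cost = _sample_kn(e_kev)
    e_sc = e_kev * eps
    theta = math.acos(cost)
    phi = TWO_PI * np.random.random()
    sx, sy, sz = _rotate(dx, dy, dz, theta, phi)
    out_kind[n] = 0
    out_e[n] = e_sc
    out_dx[n] = sx
    out_dy[n] = sy
    out_dz[n] = sz
    n += 1
    t_e = e_kev - e_sc
    if t_e > 0.0:
        pex = e_kev * dx - e_sc * sx
        pey = e_kev * dy - e_sc * sy
        pez = e_kev * dz - e_sc * sz
        pn = math.sqrt(pex * pex + pey * pey + pez * pez)
        if pn > 0.0:
            out_kind[n] = 1
            out_e[n] = t_e
            out_dx[n] = pex / pn
            out_dy[n] = pey / pn
            out_dz[n] = pez / pn
            n += 1
        else:
            return n, t_e, 1
    return n, 0.0, 1


@njit(cache=True)
def _score_site_shell(scratch, touched, nt, x, y, z, val,
                      shell_edges, int_mask, r0, idx_np, idx_other, idx_int):
    """Bin a point deposit on the radial shell grid."""
    n_shell = len(shell_edges) - 1
    r = math.sqrt(x * x + y * y + z * z)
    if r < r0:
        return _score(scratch, touched, nt, idx_np, val)
    d = r - r0
    if d >= shell_edges[n_shell]:
        return _score(scratch, touched, nt, idx_other, val)
    lo = 0
    hi = n_shell
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if shell_edges[mid] <= d:
            lo = mid
        else:
            hi = mid
    nt = _score(scratch, touched, nt, lo, val)
    if int_mask[lo] == 1:
        nt = _score(scratch, touched, nt, idx_int, val)
    return nt


@njit(cache=True)
def _score_site_regions(scratch, touched, nt, x, y, z, val, r_nuc, r_cell, idx_other):
    r = math.sqrt(x * x + y * y + z * z)
    if r <= r_nuc:
        return _score(scratch, touched, nt, 1, val)
    if r <= r_cell:
        return _score(scratch, touched, nt, 0, val)
    return _score(scratch, touched, nt, idx_other, val)


@njit(cache=True)
def run_single_np(
    pack, seed, n_hist, spec_edges, spec_cdf, beam_r, z_start,
    radii, mats, n_layers, water_mat, world_r, box_h, use_box,
    b_mag, bdx, bdy, bdz, cutoff, frac, auger, do_scatter,
    force_mode,  # 0 analog, 1 forced whole ray, 2 forced NP chord
    shell_edges, shell_widths, int_mask, r0,
    record_on, rec_x, rec_y, rec_z, rec_dx, rec_dy, rec_dz, rec_e, rec_w, rec_hist,
    sums, sums2,
):
    """Photon histories on a single nanoparticle at the origin.

    Scores the radial shell grid (and nanoparticle-internal / outside-grid
    deposits) with per-history variance; optionally records outward
    surface-crossing electrons.  Returns
    (n_records, escaped_kev, source_kev, deposited_kev, n_photoelectric, n_compton).
    """
    np.random.seed(seed)
    n_shell = len(shell_edges) - 1
    idx_np = n_shell
    idx_other = n_shell + 1
    idx_int = n_shell + 2
    nstot = n_shell + 3
    scratch = np.zeros(nstot)
    touched = np.empty(nstot, dtype=np.int64)
    region_dummy = np.zeros(2)
    # photon stack
    sx_ = np.empty(STACK)
    sy_ = np.empty(STACK)
    sz_ = np.empty(STACK)
    sdx = np.empty(STACK)
    sdy = np.empty(STACK)
    sdz = np.empty(STACK)
    se_ = np.empty(STACK)
    sw_ = np.empty(STACK)
    # secondary queue
    q_kind = np.empty(64, dtype=np.int64)
    q_e = np.empty(64)
    q_dx = np.empty(64)
    q_dy = np.empty(64)
    q_dz = np.empty(64)
    # primary segments
    max_seg = 2 * n_layers + 4
    seg_a = np.empty(max_seg)
    seg_b = np.empty(max_seg)
    seg_m = np.empty(max_seg, dtype=np.int64)
    seg_np = np.empty(max_seg, dtype=np.int64)
    zs = np.empty(max(n_layers, 1))
    hit = np.empty(max(n_layers, 1), dtype=np.int64)
    n_rec = 0
    escaped = 0.0
    source = 0.0
    dep_total = 0.0
    n_pe = 0
    n_co = 0
    for h in range(n_hist):
        nt = 0
        e0 = _sample_spec(spec_edges, spec_cdf)
        source += e0
        x, y = _disk_point(beam_r)
        b2 = x * x + y * y
        if use_box == 1:
            z_exit = box_h
        else:
            z_exit = math.sqrt(max(world_r * world_r - b2, 0.0))
        # layer half-chords
        k = 0
        for i in range(n_layers):
            rr = radii[i] * radii[i]
            if rr > b2:
                zs[k] = math.sqrt(rr - b2)
                hit[k] = i
                k += 1
        nseg = 0
        zc = z_start
        if k > 0:
            zf = -zs[k - 1]
            if zf > zc + 1e-12:
                seg_a[nseg] = zc
                seg_b[nseg] = zf
                seg_m[nseg] = water_mat
                seg_np[nseg] = 0
                nseg += 1
            zc = zf
            for j in range(k - 1, 0, -1):
                seg_a[nseg] = -zs[j]
                seg_b[nseg] = -zs[j - 1]
                seg_m[nseg] = mats[hit[j]]
                seg_np[nseg] = 1
                nseg += 1
            seg_a[nseg] = -zs[0]
            seg_b[nseg] = zs[0]
            seg_m[nseg] = mats[hit[0]]
            seg_np[nseg] = 1
            nseg += 1
            for j in range(1, k):
                seg_a[nseg] = zs[j - 1]
                seg_b[nseg] = zs[j]
                seg_m[nseg] = mats[hit[j]]
                seg_np[nseg] = 1
                nseg += 1
            zc = zs[k - 1]
        if z_exit > zc + 1e-12:
            seg_a[nseg] = zc
            seg_b[nseg] = z_exit
            seg_m[nseg] = water_mat
            seg_np[nseg] = 0
            nseg += 1
        tau_all = 0.0
        tau_np = 0.0
        for i in range(nseg):
            mu = _mu_lin_inv_nm(pack, seg_m[i], e0)
            t = mu * (seg_b[i] - seg_a[i])
            tau_all += t
            if seg_np[i] == 1:
                tau_np += t
        # choose interaction point
        have_int = 0
        w_int = 1.0
        z_int = 0.0
        m_int = water_mat
        if force_mode == 0:
            u = -math.log(max(np.random.random(), 1e-300))
            if u < tau_all:
                have_int = 1
        elif force_mode == 1:
            if tau_all > 0.0:
                p_int = 1.0 - math.exp(-tau_all)
                u = -math.log1p(-np.random.random() * p_int)
                w_int = p_int
                have_int = 1
        else:
            if tau_np > 0.0:
                p_int = 1.0 - math.exp(-tau_np)
                u = -math.log1p(-np.random.random() * p_int)
                w_int = p_int
                have_int = 1
        if have_int == 1:
            acc = u
            found = 0
            for i in range(nseg):
                if force_mode == 2 and seg_np[i] == 0:
                    continue
                mu = _mu_lin_inv_nm(pack, seg_m[i], e0)
                t = mu * (seg_b[i] - seg_a[i])
                if t >= acc:
                    z_int = seg_a[i] + (acc / mu if mu > 0.0 else 0.0)
                    m_int = seg_m[i]
                    found = 1
                    break
                acc -= t
            if found == 0:
                have_int = 0
        if have_int == 0:
            escaped += e0
            nh_fold = 0  # nothing scored
        else:
            escaped += (1.0 - w_int) * e0
            nstk = 0
            # process the forced/analog interaction
            nq, local, itype = _interact(pack, m_int, e0, 0.0, 0.0, 1.0, auger,
                                         q_kind, q_e, q_dx, q_dy, q_dz)
            if itype == 0:
                n_pe += 1
            else:
                n_co += 1
            if local > 0.0:
                nt = _score_site_shell(scratch, touched, nt, x, y, z_int, local * w_int,
                                       shell_edges, int_mask, r0, idx_np, idx_other, idx_int)
            for iq in range(nq):
                if q_kind[iq] == 1:
                    nt, n_rec, esc, ex, ey, ez, edx, edy, edz, ee = _electron_track(
                        pack, x, y, z_int, q_dx[iq], q_dy[iq], q_dz[iq], q_e[iq], w_int,
                        radii, mats, n_layers, water_mat, world_r, box_h, use_box,
                        b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                        0, shell_edges, shell_widths, int_mask, r0, region_dummy,
                        scratch, touched, nt, idx_np, idx_other, idx_int,
                        record_on, rec_x, rec_y, rec_z, rec_dx, rec_dy, rec_dz,
                        rec_e, rec_w, rec_hist, n_rec, h)
                    escaped += esc
                else:
                    if q_e[iq] < E_FLOOR:
                        nt = _score_site_shell(scratch, touched, nt, x, y, z_int,
                                               q_e[iq] * w_int, shell_edges, int_mask,
                                               r0, idx_np, idx_other, idx_int)
                    elif nstk < STACK:
                        ix, iy, iz = _isotropic()
                        sx_[nstk] = x
                        sy_[nstk] = y
                        sz_[nstk] = z_int
                        sdx[nstk] = q_dx[iq]
                        sdy[nstk] = q_dy[iq]
                        sdz[nstk] = q_dz[iq]
                        se_[nstk] = q_e[iq]
                        sw_[nstk] = w_int
                        nstk += 1
            # secondary photon cascade
            while nstk > 0:
                nstk -= 1
                gx = sx_[nstk]
                gy = sy_[nstk]
                gz = sz_[nstk]
                gdx = sdx[nstk]
                gdy = sdy[nstk]
                gdz = sdz[nstk]
                ge = se_[nstk]
                gw = sw_[nstk]
                u = -math.log(max(np.random.random(), 1e-300))
                hit_f, hx, hy, hz, hm = _photon_march_concentric(
                    pack, gx, gy, gz, gdx, gdy, gdz, ge,
                    radii, mats, n_layers, water_mat, world_r, box_h, use_box, u)
                if hit_f == 0:
                    escaped += ge * gw
                    continue
                nq, local, itype = _interact(pack, hm, ge, gdx, gdy, gdz, auger,
                                             q_kind, q_e, q_dx, q_dy, q_dz)
                if itype == 0:
                    n_pe += 1
                else:
                    n_co += 1
                if local > 0.0:
                    nt = _score_site_shell(scratch, touched, nt, hx, hy, hz, local * gw,
                                           shell_edges, int_mask, r0, idx_np, idx_other, idx_int)
                for iq in range(nq):
                    if q_kind[iq] == 1:
                        nt, n_rec, esc, ex, ey, ez, edx, edy, edz, ee = _electron_track(
                            pack, hx, hy, hz, q_dx[iq], q_dy[iq], q_dz[iq], q_e[iq], gw,
                            radii, mats, n_layers, water_mat, world_r, box_h, use_box,
                            b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                            0, shell_edges, shell_widths, int_mask, r0, region_dummy,
                            scratch, touched, nt, idx_np, idx_other, idx_int,
                            record_on, rec_x, rec_y, rec_z, rec_dx, rec_dy, rec_dz,
                            rec_e, rec_w, rec_hist, n_rec, h)
                        escaped += esc
                    else:
                        if q_e[iq] < E_FLOOR:
                            nt = _score_site_shell(scratch, touched, nt, hx, hy, hz,
                                                   q_e[iq] * gw, shell_edges, int_mask,
                                                   r0, idx_np, idx_other, idx_int)
                        elif nstk < STACK:
                            sx_[nstk] = hx
                            sy_[nstk] = hy
                            sz_[nstk] = hz
                            sdx[nstk] = q_dx[iq]
                            sdy[nstk] = q_dy[iq]
                            sdz[nstk] = q_dz[iq]
                            se_[nstk] = q_e[iq]
                            sw_[nstk] = gw
                            nstk += 1
        # fold per-history scratch
        for ii in range(nt):
            idx = touched[ii]
            v = scratch[idx]
            sums[idx] += v
            sums2[idx] += v * v
            if idx != idx_int:
                dep_total += v
            scratch[idx] = 0.0
    return n_rec, escaped, source, dep_total, n_pe, n_co


@njit(cache=True)
def run_step2(
    pack, seed, n_src,
    rx, ry, rz, rdx, rdy, rdz, re_, rw, rhist,
    world_r, b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
    shell_edges, shell_widths, int_mask, r0,
    sums, sums2,
):
    """Replay surface-electron records in a pure-water sphere (two-step, step 2).

    Records must be sorted by source-history id (< n_src); per-source-history
    grouping preserves the history-by-history variance estimator.  Returns
    (escaped_kev, source_kev, deposited_kev).
    """
    np.random.seed(seed)
    n_shell = len(shell_edges) - 1
    idx_np = n_shell
    idx_other = n_shell + 1
    idx_int = n_shell + 2
    nstot = n_shell + 3
    scratch = np.zeros(nstot)
    touched = np.empty(nstot, dtype=np.int64)
    region_dummy = np.zeros(2)
    radii0 = np.zeros(0)
    mats0 = np.zeros(0, dtype=np.int64)
    rec_d = np.zeros(1)
    rec_i = np.zeros(1, dtype=np.int64)
    escaped = 0.0
    source = 0.0
    dep_total = 0.0
    i = 0
    n_all = len(re_)
    for h in range(n_src):
        nt = 0
        while i < n_all and rhist[i] == h:
            source += re_[i] * rw[i]
            nt, _nr, esc, ex, ey, ez, edx, edy, edz, ee = _electron_track(
                pack, rx[i], ry[i], rz[i], rdx[i], rdy[i], rdz[i], re_[i], rw[i],
                radii0, mats0, 0, 0, world_r, 0.0, 0,
                b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                0, shell_edges, shell_widths, int_mask, r0, region_dummy,
                scratch, touched, nt, idx_np, idx_other, idx_int,
                0, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_i, 0, h)
            escaped += esc
            i += 1
        for ii in range(nt):
            idx = touched[ii]
            v = scratch[idx]
            sums[idx] += v
            sums2[idx] += v * v
            if idx != idx_int:
                dep_total += v
            scratch[idx] = 0.0
    return escaped, source, dep_total


@njit(cache=True)
def run_cell(
    pack, seed, n_hist, spec_edges, spec_cdf, beam_r, z_start,
    r_nuc, r_cell, world_r,
    npx, npy, npz, r_np, r_core, m_shell, m_core,
    gx0, gy0, gcell, gnx, gny, cell_start, cell_items,
    b_mag, bdx, bdy, bdz, cutoff, frac, auger, do_scatter, force_mode,
    sums, sums2,
):
    """Photon histories on the nanoparticle-loaded cell.

    Scratch/sums indices: 0 cytoplasm, 1 nucleus, 2 NP-internal, 3 other
    in-world water.  Electrons see water outside their birth nanoparticle;
    the intra-NP leg is transported in the layered particle.  Returns
    (escaped_kev, source_kev, deposited_kev, n_photoelectric, n_compton, n_np_interactions).
    """
    np.random.seed(seed)
    nstot = 5  # [cyt, nuc, np-internal, other, dummy-int]
    idx_np = 2
    idx_other = 3
    idx_int = 4
    scratch = np.zeros(nstot)
    touched = np.empty(nstot, dtype=np.int64)
    # dummies for shell-mode arguments
    shell_dummy = np.array([0.0, 1.0])
    width_dummy = np.array([1.0])
    mask_dummy = np.zeros(1, dtype=np.int64)
    region_r = np.array([r_nuc, r_cell])
    radii0 = np.zeros(0)
    mats0 = np.zeros(0, dtype=np.int64)
    rec_d = np.zeros(1)
    rec_i = np.zeros(1, dtype=np.int64)
    # birth-NP local geometry
    np_radii = np.empty(2)
    np_mats = np.empty(2, dtype=np.int64)
    if r_core > 0.0:
        np_radii[0] = r_core
        np_radii[1] = r_np
        np_mats[0] = m_core
        np_mats[1] = m_shell
        n_np_layers = 2
    else:
        np_radii[0] = r_np
        np_mats[0] = m_shell
        n_np_layers = 1
    # photon stack
    sx_ = np.empty(STACK)
    sy_ = np.empty(STACK)
    sz_ = np.empty(STACK)
    sdx = np.empty(STACK)
    sdy = np.empty(STACK)
    sdz = np.empty(STACK)
    se_ = np.empty(STACK)
    sw_ = np.empty(STACK)
    q_kind = np.empty(64, dtype=np.int64)
    q_e = np.empty(64)
    q_dx = np.empty(64)
    q_dy = np.empty(64)
    q_dz = np.empty(64)
    MAXSEG = 192
    seg_a = np.empty(MAXSEG)
    seg_b = np.empty(MAXSEG)
    seg_m = np.empty(MAXSEG, dtype=np.int64)
    order = np.empty(MAXSEG, dtype=np.int64)
    escaped = 0.0
    source = 0.0
    dep_total = 0.0
    n_pe = 0
    n_co = 0
    n_np_int = 0
    n_npa = len(npx)
    for h in range(n_hist):
        nt = 0
        e0 = _sample_spec(spec_edges, spec_cdf)
        source += e0
        x, y = _disk_point(beam_r)
        b2 = x * x + y * y
        z_exit = math.sqrt(max(world_r * world_r - b2, 1.0))
        # nanoparticle chords along the ray via the xy grid
        nseg = 0
        if n_npa > 0:
            ix = int((x - gx0) / gcell)
            iy = int((y - gy0) / gcell)
            if 0 <= ix < gnx and 0 <= iy < gny:
                c = ix * gny + iy
                for it in range(cell_start[c], cell_start[c + 1]):
                    j = cell_items[it]
                    ddx = npx[j] - x
                    ddy = npy[j] - y
                    rho2 = ddx * ddx + ddy * ddy
                    if rho2 < r_np * r_np and nseg + 3 <= MAXSEG:
                        dz = math.sqrt(r_np * r_np - rho2)
                        z1 = npz[j] - dz
                        z2 = npz[j] + dz
                        if r_core > 0.0 and rho2 < r_core * r_core:
                            dzc = math.sqrt(r_core * r_core - rho2)
                            zc1 = npz[j] - dzc
                            zc2 = npz[j] + dzc
                            seg_a[nseg] = z1
                            seg_b[nseg] = zc1
                            seg_m[nseg] = m_shell + 1000 * j
                            nseg += 1
                            seg_a[nseg] = zc1
                            seg_b[nseg] = zc2
                            seg_m[nseg] = m_core + 1000 * j
                            nseg += 1
                            seg_a[nseg] = zc2
                            seg_b[nseg] = z2
                            seg_m[nseg] = m_shell + 1000 * j
                            nseg += 1
                        else:
                            seg_a[nseg] = z1
                            seg_b[nseg] = z2
                            seg_m[nseg] = m_shell + 1000 * j
                            nseg += 1
        # sort nanoparticle segments by entry z (insertion sort)
        for a_ in range(1, nseg):
            ka = seg_a[a_]
            kb = seg_b[a_]
            km = seg_m[a_]
            b_ = a_ - 1
            while b_ >= 0 and seg_a[b_] > ka:
                seg_a[b_ + 1] = seg_a[b_]
                seg_b[b_ + 1] = seg_b[b_]
                seg_m[b_ + 1] = seg_m[b_]
                b_ -= 1
            seg_a[b_ + 1] = ka
            seg_b[b_ + 1] = kb
            seg_m[b_ + 1] = km
        mu_w = _mu_lin_inv_nm(pack, 0, e0)
        tau_all = mu_w * (z_exit - z_start)
        for i in range(nseg):
            mseg = seg_m[i] % 1000
            tau_all += (_mu_lin_inv_nm(pack, mseg, e0) - mu_w) * (seg_b[i] - seg_a[i])
        have_int = 0
        w_int = 1.0
        if force_mode == 1:
            if tau_all > 0.0:
                p_int = 1.0 - math.exp(-tau_all)
                u = -math.log1p(-np.random.random() * p_int)
                w_int = p_int
                have_int = 1
        else:
            u = -math.log(max(np.random.random(), 1e-300))
            if u < tau_all:
                have_int = 1
        z_int = 0.0
        m_int = 0
        np_idx = -1
        if have_int == 1:
            acc = u
            zc = z_start
            found = 0
            for i in range(nseg + 1):
                if i < nseg:
                    za = seg_a[i]
                    zb = seg_b[i]
                else:
                    za = z_exit
                    zb = z_exit
                # water gap before this segment
                if za > zc:
                    t = mu_w * (za - zc)
                    if acc <= t:
                        z_int = zc + acc / mu_w
                        m_int = 0
                        np_idx = -1
                        found = 1
                        break
                    acc -= t
                    zc = za
                if i < nseg:
                    mseg = seg_m[i] % 1000
                    mu_s = _mu_lin_inv_nm(pack, mseg, e0)
                    t = mu_s * (zb - zc)
                    if acc <= t:
                        z_int = zc + (acc / mu_s if mu_s > 0.0 else 0.0)
                        m_int = mseg
                        np_idx = seg_m[i] // 1000
                        found = 1
                        break
                    acc -= t
                    zc = zb
            if found == 0:
                have_int = 0
        if have_int == 0:
            escaped += e0
        else:
            escaped += (1.0 - w_int) * e0
            if np_idx >= 0:
                n_np_int += 1
            nstk = 0
            nq, local, itype = _interact(pack, m_int, e0, 0.0, 0.0, 1.0, auger,
                                         q_kind, q_e, q_dx, q_dy, q_dz)
            if itype == 0:
                n_pe += 1
            else:
                n_co += 1
            if local > 0.0:
                if np_idx >= 0:
                    nt = _score(scratch, touched, nt, idx_np, local * w_int)
                else:
                    nt = _score_site_regions(scratch, touched, nt, x, y, z_int,
                                             local * w_int, r_nuc, r_cell, idx_other)
            for iq in range(nq):
                ge = q_e[iq]
                gdx = q_dx[iq]
                gdy = q_dy[iq]
                gdz = q_dz[iq]
                if q_kind[iq] == 1:
                    exx = x
                    exy = y
                    exz = z_int
                    ee = ge
                    if np_idx >= 0:
                        # intra-nanoparticle leg in the local frame
                        nt, _nr, esc_np, lx, ly, lz, ldx, ldy, ldz, le = _electron_track(
                            pack, x - npx[np_idx], y - npy[np_idx], z_int - npz[np_idx],
                            gdx, gdy, gdz, ge, w_int,
                            np_radii, np_mats, n_np_layers, 0, r_np, 0.0, 0,
                            b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                            2, shell_dummy, width_dummy, mask_dummy, 0.0, region_r,
                            scratch, touched, nt, idx_np, idx_np, idx_int,
                            0, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_i, 0, h)
                        if le <= 0.0:
                            continue
                        exx = npx[np_idx] + lx
                        exy = npy[np_idx] + ly
                        exz = npz[np_idx] + lz
                        gdx = ldx
                        gdy = ldy
                        gdz = ldz
                        ee = le
                    nt, _nr, esc, _a, _b, _c, _d, _e, _f, _g = _electron_track(
                        pack, exx, exy, exz, gdx, gdy, gdz, ee, w_int,
                        radii0, mats0, 0, 0, world_r, 0.0, 0,
                        b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                        1, shell_dummy, width_dummy, mask_dummy, 0.0, region_r,
                        scratch, touched, nt, idx_np, idx_other, idx_int,
                        0, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_i, 0, h)
                    escaped += esc
                else:
                    if ge < E_FLOOR:
                        if np_idx >= 0:
                            nt = _score(scratch, touched, nt, idx_np, ge * w_int)
                        else:
                            nt = _score_site_regions(scratch, touched, nt, x, y, z_int,
                                                     ge * w_int, r_nuc, r_cell, idx_other)
                    elif nstk < STACK:
                        sx_[nstk] = x
                        sy_[nstk] = y
                        sz_[nstk] = z_int
                        sdx[nstk] = gdx
                        sdy[nstk] = gdy
                        sdz[nstk] = gdz
                        se_[nstk] = ge
                        sw_[nstk] = w_int
                        nstk += 1
            # secondary photons: water-only world (nanoparticles ignored)
            while nstk > 0:
                nstk -= 1
                gx = sx_[nstk]
                gy = sy_[nstk]
                gz = sz_[nstk]
                gdx = sdx[nstk]
                gdy = sdy[nstk]
                gdz = sdz[nstk]
                ge = se_[nstk]
                gw = sw_[nstk]
                u = -math.log(max(np.random.random(), 1e-300))
                hit_f, hx, hy, hz, hm = _photon_march_concentric(
                    pack, gx, gy, gz, gdx, gdy, gdz, ge,
                    radii0, mats0, 0, 0, world_r, 0.0, 0, u)
                if hit_f == 0:
                    escaped += ge * gw
                    continue
                nq, local, itype = _interact(pack, 0, ge, gdx, gdy, gdz, auger,
                                             q_kind, q_e, q_dx, q_dy, q_dz)
                if itype == 0:
                    n_pe += 1
                else:
                    n_co += 1
                if local > 0.0:
                    nt = _score_site_regions(scratch, touched, nt, hx, hy, hz,
                                             local * gw, r_nuc, r_cell, idx_other)
                for iq in range(nq):
                    if q_kind[iq] == 1:
                        nt, _nr, esc, _a, _b, _c, _d, _e, _f, _g = _electron_track(
                            pack, hx, hy, hz, q_dx[iq], q_dy[iq], q_dz[iq], q_e[iq], gw,
                            radii0, mats0, 0, 0, world_r, 0.0, 0,
                            b_mag, bdx, bdy, bdz, cutoff, frac, do_scatter,
                            1, shell_dummy, width_dummy, mask_dummy, 0.0, region_r,
                            scratch, touched, nt, idx_np, idx_other, idx_int,
                            0, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_d, rec_i, 0, h)
                        escaped += esc
                    else:
                        if q_e[iq] < E_FLOOR:
                            nt = _score_site_regions(scratch, touched, nt, hx, hy, hz,
                                                     q_e[iq] * gw, r_nuc, r_cell, idx_other)
                        elif nstk < STACK:
                            sx_[nstk] = hx
                            sy_[nstk] = hy
                            sz_[nstk] = hz
                            sdx[nstk] = q_dx[iq]
                            sdy[nstk] = q_dy[iq]
                            sdz[nstk] = q_dz[iq]
                            se_[nstk] = q_e[iq]
                            sw_[nstk] = gw
                            nstk += 1
        for ii in range(nt):
            idx = touched[ii]
            v = scratch[idx]
            sums[idx] += v
            sums2[idx] += v * v
            if idx != idx_int:
                dep_total += v
            scratch[idx] = 0.0
    return escaped, source, dep_total, n_pe, n_co, n_np_int
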