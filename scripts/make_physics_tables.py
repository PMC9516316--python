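"""Regenerate the packaged photoelectric cross-section tables.

The packaged CSV is produced from hand-curated anchor values of the
photoelectric mass attenuation coefficient (cm^2/g) per element, consistent
with standard compilations (NIST XCOM grade, ~10%).  Anchors are densified to
a log-spaced node grid with log-log interpolation; absorption-edge nodes are
duplicated so interpolation preserves the discontinuity.  Gold's M-subshell
structure is folded into a monotone envelope below the L edge and the three
L edges are merged into a single effective edge, matching the
single-generation relaxation model used by the transport code.

Run from the repository root:  python scripts/make_physics_tables.py
"""

import csv
import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "nanodef" / "physics" / "data"

# (energy keV, tau/rho cm^2/g); edge energies appear twice (below+, above-)
ANCHORS = {
    "H": [
        (1.0, 6.8), (1.5, 1.92), (2.0, 0.77), (3.0, 0.205), (4.0, 0.080),
        (5.0, 0.0385), (6.0, 0.0213), (8.0, 0.0082), (10.0, 0.0039),
        (15.0, 0.00104), (20.0, 4.0e-4), (30.0, 1.05e-4), (40.0, 4.1e-5),
        (50.0, 2.0e-5), (80.0, 4.5e-6), (100.0, 2.2e-6), (150.0, 6.0e-7),
        (200.0, 2.4e-7), (300.0, 7.0e-8), (500.0, 1.5e-8), (900.0, 2.7e-9),
    ],
    "O": [
        (1.0, 4550.0), (1.5, 1570.0), (2.0, 690.0), (3.0, 218.0), (4.0, 91.0),
        (5.0, 46.5), (6.0, 26.8), (8.0, 11.0), (10.0, 5.45), (15.0, 1.55),
        (20.0, 0.624), (30.0, 0.174), (40.0, 0.070), (50.0, 0.0337),
        (60.0, 0.0185), (80.0, 0.00745), (100.0, 0.00365), (150.0, 0.00100),
        (200.0, 4.1e-4), (300.0, 1.22e-4), (400.0, 5.2e-5), (500.0, 2.7e-5),
        (600.0, 1.6e-5), (800.0, 7.0e-6), (900.0, 5.2e-6),
    ],
    "Fe": [
        (1.0, 9050.0), (1.5, 3380.0), (2.0, 1610.0), (3.0, 548.0), (4.0, 250.0),
        (5.0, 134.0), (6.0, 80.0), (7.112, 50.5),     # K edge below
        (7.112, 398.0),                                # K edge above
        (8.0, 297.0), (10.0, 162.0), (15.0, 51.5), (20.0, 22.6), (30.0, 7.35),
        (40.0, 3.15), (50.0, 1.70), (60.0, 1.00), (80.0, 0.435), (100.0, 0.226),
        (150.0, 0.066), (200.0, 0.027), (300.0, 0.0083), (400.0, 0.0036),
        (500.0, 0.0019), (600.0, 0.0011), (800.0, 5.2e-4), (900.0, 3.9e-4),
    ],
    "Au": [
        (1.0, 4600.0), (1.5, 2600.0), (2.0, 1600.0), (3.0, 1450.0),
        (4.0, 1050.0), (5.0, 720.0), (6.0, 480.0), (8.0, 230.0), (10.0, 125.0),
        (11.919, 78.0),                                # effective L edge below
        (11.919, 295.0),                               # effective L edge above
        (15.0, 164.0), (20.0, 78.8), (30.0, 25.7), (40.0, 11.8), (50.0, 6.65),
        (60.0, 4.10), (80.725, 1.93),                  # K edge below
        (80.725, 8.30),                                # K edge above
        (100.0, 4.92), (150.0, 1.81), (200.0, 0.90), (300.0, 0.302),
        (400.0, 0.145), (500.0, 0.0845), (600.0, 0.0560), (800.0, 0.0302),
        (900.0, 0.0240),
    ],
}

EDGES = {"Fe": [7.112], "Au": [11.919, 80.725]}

N_NODES_PER_DECADE = 22


def densify(anchors, edges):
    """Log-spaced nodes within each inter-edge segment, log-log interpolated."""
    e = np.array([a[0] for a in anchors])
    v = np.array([a[1] for a in anchors])
    bounds = [1.0] + list(edges) + [900.0]
    rows = []
    start = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        # anchor slice for this segment (inclusive of duplicated edge rows)
        idx = [i for i in range(len(e)) if lo <= e[i] <= hi]
        # drop the duplicate rows belonging to the neighbouring segment
        if lo in edges:
            idx = idx[1:] if e[idx[0]] == lo and e[idx[1]] == lo else idx
        if hi in edges:
            if e[idx[-1]] == hi and e[idx[-2]] == hi:
                idx = idx[:-1]
        seg_e, seg_v = e[idx], v[idx]
        n = max(4, int(np.ceil(np.log10(hi / lo) * N_NODES_PER_DECADE)))
        nodes = np.geomspace(lo, hi, n)
        nodes[0], nodes[-1] = lo, hi
        vals = np.exp(np.interp(np.log(nodes), np.log(seg_e), np.log(seg_v)))
        rows.extend(zip(nodes, vals))
        start += 1
    return rows


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / "photoelectric.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["element", "energy_kev", "mu_pe_cm2_per_g"])
        for sym, anchors in ANCHORS.items():
            for energy, val in densify(anchors, EDGES.get(sym, [])):
                w.writerow([sym, f"{energy:.9g}", f"{val:.6g}"])
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
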