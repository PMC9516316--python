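"""Matplotlib helpers for dose profiles, DEF curves and spectra."""

from __future__ import annotations

import numpy as np


def plot_dose_profile(profiles, ax=None, logx=True, logy=True):
    """Overlay shell dose profiles (dict label -> ShellDoseProfile)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, prof in profiles.items():
        dose, se = prof.dose_gy_per_source()
        mid = 0.5 * (prof.grid.edges_nm[:-1] + prof.grid.edges_nm[1:])
        ok = dose > 0
        ax.errorbar(mid[ok], dose[ok], yerr=se[ok], label=label, lw=0.8, errorevery=10)
    if logx:
        ax.set_xscale("log")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("distance from NP surface (nm)")
    ax.set_ylabel("dose (Gy per source photon)")
    ax.legend()
    return ax


def plot_def_curve(curve, ax=None, logx=True):
    """Plot def_curve output: list of (lo, hi, DEFResult)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mid = np.array([(lo + hi) / 2 for lo, hi, _ in curve])
    val = np.array([r.value for _, _, r in curve])
    err = np.array([r.stderr for _, _, r in curve])
    ax.errorbar(mid, val, yerr=err, lw=0.8, errorevery=10)
    ax.axhline(1.0, color="grey", lw=0.5)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel("distance from NP surface (nm)")
    ax.set_ylabel("DEF")
    return ax


def plot_spectrum(tallies, ax=None):
    """Step plot of surface electron spectra (dict label -> ElectronSpectrumTally)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, t in tallies.items():
        ax.stairs(t.counts_per_photon, t.edges_kev, label=f"{label} ({t.auger_label})")
    ax.set_yscale("log")
    ax.set_xlabel("electron energy (keV)")
    ax.set_ylabel("electrons per source photon per bin")
    ax.legend()
    return ax
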