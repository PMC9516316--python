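"""Study pipelines: the five simulation designs behind one interface.

* two-step: record electrons leaving the nanoparticle surface (step 1, 200 nm
  water box), replay them from the centre of the 20 um water sphere (step 2),
  score the radial shell grid; DEF against the water-nanoparticle (WNP) arm.
* one-step: direct photon + nanoparticle + water simulation, same scoring.
* cell: nanoparticle-loaded 10 um cell, cytoplasm and nucleus DEFs against a
  zero-nanoparticle baseline run with the same seed stream.
* bscan: magnetic-field scan with doubled beam diameters.
* brachy: Ir-192-like spectrum source; plain, targeted (1.48x) and solid-gold
  arms.
* escan: monoenergetic energy scan with trend diagnostics.

Every pipeline is deterministic under (seed, config); per-arm seeds derive
from numpy SeedSequence so arms are independent unless a baseline explicitly
reuses a stream (common random numbers).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import constants as const
from . import engine
from .materials import (
    CellModel,
    NP_MODELS,
    cell_volume_ml,
    np_count_from_concentration,
    place_nanoparticles,
)
from .scoring import DEFResult, def_curve, integrated_def, region_def, surface_spectrum
from .sources import EnergySpectrum, make_ir192_like_spectrum
from .transport import MagneticFieldSpec, gyroradius_mm

DEFAULT_ENERGIES_KEV = (50.0, 100.0, 150.0, 200.0, 250.0)
DEFAULT_CONCENTRATIONS = (5.0, 10.0, 50.0)
DEFAULT_SINGLE_NP_HISTORIES = 1_000_000
DEFAULT_CELL_HISTORIES = 200_000
DEFAULT_PLACEMENT_SEEDS = 3


def derive_seed(seed: int, *tags) -> int:
    """Stable sub-seed (< 2^31) for a named arm of a run."""
    h = hashlib.sha256(("/".join(str(t) for t in tags)).encode()).digest()
    entropy = int.from_bytes(h[:4], "little")
    return int(np.random.SeedSequence([seed, entropy]).generate_state(1)[0] % (2**31 - 1))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class SimulationConfig:
    """Declarative description of one pipeline run."""

    pipeline: str
    np_model: str = "core-shell"
    energy_kev: float = 50.0
    spectrum: EnergySpectrum | None = None
    concentration_mg_ml: float = 50.0
    histories: int = DEFAULT_SINGLE_NP_HISTORIES
    seed: int = 1
    beam_diameter_nm: float | None = None   # default: NP diameter / cell diameter
    b_tesla: float = 0.0
    auger: bool = True
    cutoff_kev: float = 1.0
    substep_fraction: float = 0.05
    placement_seeds: int = DEFAULT_PLACEMENT_SEEDS

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.spectrum is not None:
            d["spectrum"] = self.spectrum.label
        return d


@dataclass
class RunResult:
    """Config echo, DEF statistics and tallies of one pipeline run."""

    config: dict
    def_results: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    tallies: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0
    histories: int = 0
    runtime_s: float = 0.0

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def summary(self) -> dict:
        out = {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "histories": self.histories,
            "runtime_s": round(self.runtime_s, 2),
            "def": {
                k: {"value": v.value, "stderr": v.stderr, "scope": v.scope}
                for k, v in self.def_results.items()
            },
            "diagnostics": self.diagnostics,
        }
        return out


def _bfield(b_tesla: float) -> MagneticFieldSpec | None:
    if not b_tesla:
        return None
    # perpendicular to the +z beam
    return MagneticFieldSpec(b_tesla, (1.0, 0.0, 0.0))


def _source(config: SimulationConfig):
    return config.spectrum if config.spectrum is not None else config.energy_kev


def run_two_step(config: SimulationConfig, keep_phase_space: bool = True) -> RunResult:
    """Two-step DEF: step-1 surface recording, step-2 replay, WNP baseline."""
    t0 = time.time()
    src = _source(config)
    beam_r = (config.beam_diameter_nm or 2 * const.NP_RADIUS_NM) / 2.0
    b = _bfield(config.b_tesla)
    arms = {}
    for label in (config.np_model, "water"):
        model = NP_MODELS[label]()
        s1 = engine.run_single_np(
            model, src, config.histories, seed=derive_seed(config.seed, "step1", label),
            beam_radius_nm=beam_r, world="box", force_mode=2, record_surface=True,
            b_field=b, cutoff_kev=config.cutoff_kev, fine_scoring=False,
            substep_fraction=config.substep_fraction, auger=config.auger, label=label,
        )
        s2 = engine.run_step2(
            s1.phase_space, seed=derive_seed(config.seed, "step2", label),
            b_field=b, cutoff_kev=config.cutoff_kev,
            substep_fraction=config.substep_fraction, label=label,
        )
        arms[label] = (s1, s2)
    s1_np, s2_np = arms[config.np_model]
    s1_w, s2_w = arms["water"]
    result = RunResult(config.as_dict(), seed=config.seed, histories=config.histories)
    result.def_results["integrated"] = integrated_def(s2_np.profile, s2_w.profile)
    result.profiles = {config.np_model: s2_np.profile, "water": s2_w.profile}
    if keep_phase_space:
        result.tallies["phase_space"] = {config.np_model: s1_np.phase_space,
                                         "water": s1_w.phase_space}
        result.tallies["spectrum"] = {
            lbl: surface_spectrum(arms[lbl][0].phase_space,
                                  auger_label="auger-on" if config.auger else "auger-off")
            for lbl in arms
        }
    result.diagnostics = {
        "surface_electrons_per_photon": {
            lbl: float(arms[lbl][0].phase_space.weight.sum()) / config.histories
            for lbl in arms
        },
        "def_curve": def_curve(s2_np.profile, s2_w.profile),
    }
    result.runtime_s = time.time() - t0
    return result


def run_one_step(config: SimulationConfig) -> RunResult:
    """Direct in-situ simulation with shell scoring; DEF against the WNP arm.

    As in the two-step method, the scored dose is the dose produced by the
    nanoparticle's own interactions (the photon interaction is forced inside
    the particle); electron transport then sees the real layered particle,
    which is what distinguishes the methods near the surface.
    """
    t0 = time.time()
    src = _source(config)
    beam_r = (config.beam_diameter_nm or 2 * const.NP_RADIUS_NM) / 2.0
    b = _bfield(config.b_tesla)
    arms = {}
    for label in (config.np_model, "water"):
        model = NP_MODELS[label]()
        arms[label] = engine.run_single_np(
            model, src, config.histories, seed=derive_seed(config.seed, "one-step", label),
            beam_radius_nm=beam_r, world="sphere", force_mode=2, record_surface=False,
            b_field=b, cutoff_kev=config.cutoff_kev,
            substep_fraction=config.substep_fraction, auger=config.auger, label=label,
        )
    result = RunResult(config.as_dict(), seed=config.seed, histories=config.histories)
    result.def_results["integrated"] = integrated_def(
        arms[config.np_model].profile, arms["water"].profile)
    result.profiles = {lbl: arms[lbl].profile for lbl in arms}
    result.diagnostics["def_curve"] = def_curve(
        arms[config.np_model].profile, arms["water"].profile)
    result.runtime_s = time.time() - t0
    return result


def run_cell(config: SimulationConfig, explicit_count: int | None = None) -> RunResult:
    """Cell-model DEFs (cytoplasm, nucleus) against the zero-NP baseline.

    Nanoparticle placements are averaged over ``config.placement_seeds``
    random configurations with pooled statistics; the baseline run reuses the
    same kernel seed per placement (common random numbers).
    """
    t0 = time.time()
    src = _source(config)
    model = NP_MODELS[config.np_model]()
    count = (
        explicit_count
        if explicit_count is not None
        else np_count_from_concentration(config.concentration_mg_ml, cell_volume_ml(), model)
    )
    beam_r_um = (config.beam_diameter_nm / 2.0 * 1e-3) if config.beam_diameter_nm else None
    b = _bfield(config.b_tesla)
    n_place = max(1, config.placement_seeds if count > 0 else 1)
    n_per = int(np.ceil(config.histories / n_place))
    with_np = None
    baseline = None
    n_np_int = 0
    for ip in range(n_place):
        kseed = derive_seed(config.seed, "cell", ip)
        cell = CellModel(np_model=model)
        if count > 0:
            cell.np_positions_um = place_nanoparticles(
                count, cell, seed=derive_seed(config.seed, "placement", ip))
        run_w = engine.run_cell(
            cell, src, n_per, seed=kseed, beam_radius_um=beam_r_um, b_field=b,
            cutoff_kev=config.cutoff_kev, substep_fraction=config.substep_fraction,
            auger=config.auger, label=config.np_model,
        )
        cell0 = CellModel(np_model=model)
        run_0 = engine.run_cell(
            cell0, src, n_per, seed=kseed, beam_radius_um=beam_r_um, b_field=b,
            cutoff_kev=config.cutoff_kev, substep_fraction=config.substep_fraction,
            auger=config.auger, label="baseline",
        )
        n_np_int += run_w.n_np_interactions
        if with_np is None:
            with_np, baseline = run_w.tally, run_0.tally
        else:
            for tgt, add in ((with_np, run_w.tally), (baseline, run_0.tally)):
                tgt.sums += add.sums
                tgt.sums2 += add.sums2
                tgt.n_histories += add.n_histories
                tgt.np_internal_kev += add.np_internal_kev
    result = RunResult(config.as_dict(), seed=config.seed, histories=with_np.n_histories)
    if count == 0:
        # identical runs: DEF exactly one by construction
        result.def_results["cytoplasm"] = DEFResult(1.0, 0.0, 1.0, 1.0, "cytoplasm")
        result.def_results["nucleus"] = DEFResult(1.0, 0.0, 1.0, 1.0, "nucleus")
    else:
        result.def_results["cytoplasm"] = region_def(with_np, baseline, "cytoplasm")
        result.def_results["nucleus"] = region_def(with_np, baseline, "nucleus")
    result.tallies = {"with_np": with_np, "baseline": baseline}
    result.diagnostics = {
        "np_count": count,
        "np_interactions": n_np_int,
        "placements": n_place,
    }
    result.runtime_s = time.time() - t0
    return result


def run_bfield_scan(config: SimulationConfig, b_list=(0.0, 0.1, 0.2, 1.0, 10.0),
                    mode: str = "single-np") -> RunResult:
    """DEF vs magnetic field with doubled beam diameter; 0 T is the reference."""
    t0 = time.time()
    if 0.0 not in b_list:
        b_list = (0.0,) + tuple(b_list)
    results = {}
    gyro = {}
    for b_val in b_list:
        sub = SimulationConfig(**{**config.as_dict(), "pipeline": mode, "b_tesla": b_val,
                                  "spectrum": config.spectrum})
        if mode == "cell":
            sub.beam_diameter_nm = config.beam_diameter_nm or 4 * const.CELL_RADIUS_UM * 1e3
            out = run_cell(sub)
            results[b_val] = out.def_results["cytoplasm"]
        else:
            sub.beam_diameter_nm = config.beam_diameter_nm or 4 * const.NP_RADIUS_NM
            out = run_two_step(sub, keep_phase_space=False)
            results[b_val] = out.def_results["integrated"]
        gyro[b_val] = gyroradius_mm(config.energy_kev, b_val) if b_val else float("inf")
    ref = results[0.0]
    equivalence = {}
    for b_val, r in results.items():
        if b_val == 0.0:
            continue
        diff = r.value - ref.value
        sigma = float(np.hypot(r.stderr, ref.stderr))
        equivalence[b_val] = {"delta": diff, "sigma": sigma,
                              "within_2sigma": bool(abs(diff) <= 2 * sigma)}
    result = RunResult(config.as_dict(), seed=config.seed, histories=config.histories)
    result.def_results = {f"B={b_val:g}T": r for b_val, r in results.items()}
    result.diagnostics = {"gyroradius_mm": gyro, "equivalence_vs_B0": equivalence,
                          "mode": mode}
    result.runtime_s = time.time() - t0
    return result


def resolve_targeted_concentration(
    concentration_mg_ml: float = 50.0,
    uptake_factor: float = const.MAGNETIC_UPTAKE_FACTOR,
) -> float:
    """Magnetically targeted concentration: base concentration times uptake."""
    return concentration_mg_ml * uptake_factor


def run_brachy(config: SimulationConfig, spectrum: EnergySpectrum | None = None) -> RunResult:
    """Brachytherapy-spectrum cell study: plain, solid-gold and targeted arms."""
    t0 = time.time()
    spec = spectrum or config.spectrum or make_ir192_like_spectrum()
    c0 = config.concentration_mg_ml
    targeted = resolve_targeted_concentration(c0)
    arms = {
        "core-shell": ("core-shell", c0),
        "solid-gold": ("solid-gold", c0),
        "targeted-core-shell": ("core-shell", targeted),
    }
    result = RunResult(config.as_dict(), seed=config.seed, histories=config.histories)
    result.diagnostics["targeted_concentration_mg_ml"] = targeted
    result.diagnostics["spectrum_mean_kev"] = spec.mean_energy_kev
    for name, (model, conc) in arms.items():
        sub = SimulationConfig(**{**config.as_dict(), "pipeline": "cell",
                                  "np_model": model, "spectrum": spec,
                                  "concentration_mg_ml": conc})
        out = run_cell(sub)
        result.def_results[f"{name}/cytoplasm"] = out.def_results["cytoplasm"]
        result.def_results[f"{name}/nucleus"] = out.def_results["nucleus"]
    result.runtime_s = time.time() - t0
    return result


def run_energy_scan(config: SimulationConfig, energies=DEFAULT_ENERGIES_KEV,
                    mode: str = "two-step") -> RunResult:
    """Integrated DEF (single NP) or region DEFs (cell) across beam energies."""
    t0 = time.time()
    if len(energies) < 2:
        raise ValueError("an energy scan needs at least two energies")
    result = RunResult(config.as_dict(), seed=config.seed, histories=config.histories)
    values = {}
    for e in energies:
        sub = SimulationConfig(**{**config.as_dict(), "pipeline": mode,
                                  "energy_kev": float(e), "spectrum": None})
        if mode == "cell":
            out = run_cell(sub)
            result.def_results[f"{e:g}keV/cytoplasm"] = out.def_results["cytoplasm"]
            result.def_results[f"{e:g}keV/nucleus"] = out.def_results["nucleus"]
            values[e] = out.def_results["cytoplasm"].value
        else:
            runner = run_two_step if mode == "two-step" else run_one_step
            out = runner(sub) if mode == "one-step" else runner(sub, keep_phase_space=False)
            result.def_results[f"{e:g}keV/integrated"] = out.def_results["integrated"]
            values[e] = out.def_results["integrated"].value
    peak = max(values, key=values.get)
    tail = sorted(values)[2:]
    result.diagnostics = {
        "peak_energy_kev": float(peak),
        "tail_monotone_decreasing": bool(
            all(values[a] >= values[b] for a, b in zip(tail, tail[1:]))
        ),
        "def_by_energy": {f"{k:g}": values[k] for k in sorted(values)},
        "mode": mode,
    }
    result.runtime_s = time.time() - t0
    return result
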