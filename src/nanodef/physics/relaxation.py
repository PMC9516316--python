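"""Atomic relaxation after inner-shell ionization.

Single-generation cascade with effective shell energies: a K vacancy either
fluoresces (photon at the K-L transition energy, the K-alpha proxy) or emits
a KLL Auger electron, leaving L vacancies that relax one generation further
(L-M fluorescence or LMM Auger); remaining binding energy is deposited
locally.  Yields and binding energies are embedded per element.  With the
Auger/de-excitation toggle off, the whole vacancy energy deposits locally and
no quanta are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import ELEMENT_EDGES_KEV


@dataclass(frozen=True)
class EmittedQuantum:
    kind: str       # "photon" | "electron"
    energy_kev: float


@dataclass(frozen=True)
class RelaxationOutcome:
    quanta: tuple           # EmittedQuantum, possibly empty
    local_deposit_kev: float


# fluorescence yields per vacancy
FLUORESCENCE_YIELD = {
    "H": {"K": 0.0},
    "O": {"K": 0.0083},
    "Fe": {"K": 0.34, "L": 0.006},
    "Au": {"K": 0.96, "L": 0.34},
}


@dataclass(frozen=True)
class AtomicRelaxationData:
    """Binding energies (keV) and fluorescence yields for one element."""

    element: str
    binding_kev: dict
    fluorescence_yield: dict

    def __post_init__(self):
        shells = [s for s in ("K", "L", "M") if s in self.binding_kev]
        energies = [self.binding_kev[s] for s in shells]
        if any(e <= 0 for e in energies) or any(
            a <= b for a, b in zip(energies, energies[1:])
        ):
            raise ValueError(f"binding energies must be positive and K > L > M: {self}")
        if any(not 0.0 <= y <= 1.0 for y in self.fluorescence_yield.values()):
            raise ValueError("fluorescence yields must lie in [0, 1]")


RELAXATION_DATA = {
    sym: AtomicRelaxationData(sym, ELEMENT_EDGES_KEV[sym], FLUORESCENCE_YIELD[sym])
    for sym in ELEMENT_EDGES_KEV
}

_NEXT_SHELL = {"K": "L", "L": "M", "M": None}


def _relax_one(data: AtomicRelaxationData, shell: str, rng, quanta, depth: int) -> float:
    """Relax one vacancy; append quanta, return locally deposited energy (keV)."""
    b = data.binding_kev[shell]
    lower = _NEXT_SHELL.get(shell)
    if lower is None or lower not in data.binding_kev or depth > 2:
        return b  # no lower shell modelled: binding energy deposits locally
    b_low = data.binding_kev[lower]
    omega = data.fluorescence_yield.get(shell, 0.0)
    if rng.random() < omega:
        quanta.append(EmittedQuantum("photon", b - b_low))
        return _relax_one(data, lower, rng, quanta, depth + 1)
    # Auger branch needs two electrons in the lower shell
    if b - 2.0 * b_low <= 0:
        return b
    quanta.append(EmittedQuantum("electron", b - 2.0 * b_low))
    deposit = 0.0
    for _ in range(2):
        deposit += _relax_one(data, lower, rng, quanta, depth + 1)
    return deposit


def relax_vacancy(
    element: str,
    shell: str,
    rng: np.random.Generator,
    auger_enabled: bool = True,
) -> RelaxationOutcome:
    """Relax an inner-shell vacancy; energy is conserved exactly.

    Sum of emitted quanta energies plus the local deposit equals the shell
    binding energy.
    """
    if element not in RELAXATION_DATA:
        raise KeyError(f"no relaxation data for element {element!r}")
    data = RELAXATION_DATA[element]
    if shell not in data.binding_kev:
        raise KeyError(f"element {element} has no shell {shell!r}")
    if not auger_enabled:
        return RelaxationOutcome((), data.binding_kev[shell])
    quanta: list = []
    deposit = _relax_one(data, shell, rng, quanta, 0)
    return RelaxationOutcome(tuple(quanta), deposit)
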