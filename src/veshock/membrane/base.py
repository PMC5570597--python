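"""Membrane-model interface shared by the ionic models.

A membrane model is a stateful object vectorised over ``n`` nodes:

``initial_state(n)``
    dict of named state arrays (gates, concentrations, pore density).
``step(Vm, state, dt, stim=0.0) -> I_ion``
    computes the total ionic current density (µA/cm², outward positive)
    from the current ``(Vm, state)`` and advances ``state`` in place by
    ``dt`` ms (gates by exponential Rush-Larsen updates, concentrations
    and pore density explicitly).  The caller advances ``Vm`` explicitly:
    ``Vm += dt * (-I_ion + J_stim) / Cm``.

Gating variables live in [0, 1] by construction of the Rush-Larsen
update; concentrations must stay positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: state keys treated as gating variables (unit interval) when validating
GATES_01 = frozenset({
    "m", "h", "j", "d", "f", "f2", "fcass", "r", "s", "xs", "xr1", "xr2",
    "rbar", "w",
})
CONCENTRATIONS = frozenset({"cai", "casr", "cass", "nai", "ki"})


@dataclass
class MembraneParams:
    """Cross-model membrane parameters.

    Cm in µF/cm².  ``k_aug_threshold`` is the activation threshold (mV) of
    the hypothetical outward K+ current recruited at large positive
    polarisations; electroporation/K augmentation can be toggled
    independently.
    """

    Cm: float = 1.0
    electroporation: bool = True
    k_current: bool = True
    k_aug_threshold: float = 160.0
    scales: dict = field(default_factory=dict)  # conductance multipliers

    def __post_init__(self):
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")


def validate_state(state: dict[str, np.ndarray]) -> None:
    """Raise ValueError on gates outside [0,1] or non-positive concentrations."""
    for k, v in state.items():
        if k in GATES_01:
            if np.any((v < -1e-12) | (v > 1 + 1e-12)):
                raise ValueError(f"gating variable {k!r} outside [0, 1]")
        elif k in CONCENTRATIONS:
            if np.any(v <= 0):
                raise ValueError(f"concentration {k!r} must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"state variable {k!r} is not finite")


def check_vm(Vm) -> None:
    if not np.all(np.isfinite(Vm)):
        raise ValueError("non-finite transmembrane potential")


def rush_larsen(x: np.ndarray, x_inf, tau, dt: float) -> np.ndarray:
    """Exponential gate update; unconditionally keeps x in [0, 1]."""
    return x_inf + (x - x_inf) * np.exp(-dt / tau)
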