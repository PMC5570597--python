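"""Fast reduced membranes for solver unit tests.

Neither model is used for headline physiology; they exist so that solver
properties (cable decay, equal-anisotropy equivalence, polarity
antisymmetry) can be tested quickly and, for the passive membrane,
against closed forms.
"""
from __future__ import annotations

import numpy as np

from .base import check_vm


class PassiveMembrane:
    """Linear leak: I_ion = Gm (Vm - Vrest).

    With membrane conductance Gm (mS/cm²) the steady cable length constant
    is lambda = sqrt(sigma_m / (beta * Gm)).
    """

    name = "passive"

    def __init__(self, g_m: float = 0.1, v_rest: float = -85.0):
        self.g_m = g_m
        self.v_rest = v_rest

    def initial_state(self, n: int) -> dict[str, np.ndarray]:
        return {}

    def initial_vm(self, n: int) -> np.ndarray:
        return np.full(n, self.v_rest, dtype=float)

    def ionic_current(self, Vm, state):
        check_vm(Vm)
        return self.g_m * (np.asarray(Vm, dtype=float) - self.v_rest)

    def step(self, Vm, state, dt: float, stim=0.0):
        if dt <= 0:
            raise ValueError("dt must be positive")
        return self.ionic_current(Vm, state)


class ReducedExcitable:
    """Two-variable excitable membrane (cubic activation + slow recovery).

    A dimensionless activator u in [0, 1] is mapped to voltage by
    ``Vm = v_rest + v_amp * u``; the recovery variable w gates a linear
    repolarising term.  Solver tests only need propagation and recovery,
    not human AP morphology.
    """

    name = "reduced_test"

    def __init__(self, k: float = 8.0, a: float = 0.15, eps: float = 0.01,
                 v_rest: float = -85.0, v_amp: float = 100.0,
                 t_scale: float = 8.0):
        self.k, self.a, self.eps = k, a, eps
        self.v_rest, self.v_amp = v_rest, v_amp
        self.t_scale = t_scale

    def initial_state(self, n: int) -> dict[str, np.ndarray]:
        return {"w": np.zeros(n)}

    def initial_vm(self, n: int) -> np.ndarray:
        return np.full(n, self.v_rest, dtype=float)

    def ionic_current(self, Vm, state):
        check_vm(Vm)
        u = (np.asarray(Vm, dtype=float) - self.v_rest) / self.v_amp
        du = (self.k * u * (u - self.a) * (1.0 - u) - u * state["w"]) / self.t_scale
        return -self.v_amp * du  # outward-positive, µA/cm² with Cm = 1

    def step(self, Vm, state, dt: float, stim=0.0):
        if dt <= 0:
            raise ValueError("dt must be positive")
        i_ion = self.ionic_current(Vm, state)
        u = (np.asarray(Vm, dtype=float) - self.v_rest) / self.v_amp
        uc = np.clip(u, 0.0, 1.5)
        dw = self.eps * (self.k * uc - state["w"]) / self.t_scale
        state["w"] = state["w"] + dt * dw
        return i_ion
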