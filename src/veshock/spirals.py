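"""Synthetic rotor fields: analytic spiral/scroll frames with known
singularity content.

Used as the independent oracle bed for filament detection: an Archimedean
spiral phase field ``chi = sum_i c_i * (atan2(y-yi, x-xi) - k r_i) + w t``
mapped to voltage by ``Vm = -20 + A cos(chi)`` has its -20 mV isosurface
exactly on ``cos chi = 0`` and its dVm/dt zero set exactly on
``sin chi = 0``; the two intersect only at the phase singularities, one
per spiral centre, with topological charge equal to the chirality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpiralField:
    centers: list[tuple[float, float]]      # node-index coordinates
    chirality: list[int]                    # ±1 per centre
    k: float = 0.15                         # radial wavenumber (rad/node)
    omega: float = 0.5                      # rotation rate (rad/ms)
    amplitude: float = 65.0                 # mV about the -20 mV level
    level: float = -20.0

    def phase(self, shape: tuple[int, int], t: float) -> np.ndarray:
        ii, jj = np.indices(shape).astype(float)
        chi = np.full(shape, self.omega * t)
        for (ci, cj), c in zip(self.centers, self.chirality):
            dx, dy = ii - ci, jj - cj
            chi += c * np.arctan2(dy, dx) - self.k * np.hypot(dx, dy)
        return chi

    def frames(self, shape: tuple[int, int], t: float,
               dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(vm_now, vm_prev) nodal frames separated by dt ms."""
        vm_now = self.level + self.amplitude * np.cos(self.phase(shape, t))
        vm_prev = self.level + self.amplitude * np.cos(self.phase(shape, t - dt))
        return vm_now, vm_prev

    def extruded_frames(self, shape: tuple[int, int], n_layers: int, t: float,
                        dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Scroll-wave frames: the 2-D field replicated through n_layers."""
        a, b = self.frames(shape, t, dt)
        return (np.repeat(a[:, :, None], n_layers, axis=2),
                np.repeat(b[:, :, None], n_layers, axis=2))


def random_spiral_suite(n_cases: int, shape: tuple[int, int] = (48, 48),
                        seed: int = 0, max_spirals: int = 3,
                        min_separation: float = 16.0) -> list[SpiralField]:
    """Reproducible random configurations of 1..max_spirals spirals.

    Centres are kept away from the boundary and from each other so each
    singularity is resolvable on the grid.
    """
    rng = np.random.default_rng(seed)
    cases = []
    margin = 10.0
    for _ in range(n_cases):
        n_sp = int(rng.integers(1, max_spirals + 1))
        centers: list[tuple[float, float]] = []
        while len(centers) < n_sp:
            c = (float(rng.uniform(margin, shape[0] - margin)),
                 float(rng.uniform(margin, shape[1] - margin)))
            if all(np.hypot(c[0] - a, c[1] - b) >= min_separation
                   for a, b in centers):
                centers.append(c)
        chir = [int(rng.choice([-1, 1])) for _ in range(n_sp)]
        cases.append(SpiralField(centers=centers, chirality=chir,
                                 k=float(rng.uniform(0.08, 0.2)),
                                 omega=float(rng.uniform(0.3, 0.8))))
    return cases


def figure_of_eight(shape: tuple[int, int] = (48, 48),
                    separation: float = 18.0) -> SpiralField:
    """Two counter-rotating spirals: the classic figure-of-eight pattern."""
    cx, cy = shape[0] / 2.0, shape[1] / 2.0
    return SpiralField(
        centers=[(cx - separation / 2.0, cy), (cx + separation / 2.0, cy)],
        chirality=[1, -1])
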