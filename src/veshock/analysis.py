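"""Quantitative outputs: activation fractions, filaments, VE polarity,
electrode resistance, shock energy and field strength.

Conventions follow the shock-response literature: tissue is *activated*
when nodal Vm exceeds -20 mV and *hyperpolarised* below -80 mV; scroll-
wave filaments are the loci where the Vm = -20 mV isosurface meets the
dVm/dt = 0 surface, counted as connected components per frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import LabeledGrid
from .solver import TissueOperators, SimState

ACTIVATION_MV = -20.0
HYPERPOL_MV = -80.0


# ======================================================================
# threshold fractions
# ======================================================================

@dataclass
class ActivationSummary:
    region: str
    sample_time: float
    fraction_activated: float       # % of region nodes with Vm > -20 mV
    fraction_hyperpolarised: float  # % with Vm < -80 mV


def threshold_fraction(vm: np.ndarray, region: np.ndarray, threshold: float,
                       direction: str = "above") -> float:
    """Percentage of region entries strictly beyond ``threshold``."""
    region = np.asarray(region)
    vals = vm[region] if region.dtype != np.bool_ else vm[region]
    if vals.size == 0:
        raise ValueError("empty region")
    if direction == "above":
        n = int(np.count_nonzero(vals > threshold))
    elif direction == "below":
        n = int(np.count_nonzero(vals < threshold))
    else:
        raise ValueError("direction must be 'above' or 'below'")
    return 100.0 * n / vals.size


def activation_summary(vm_tissue: np.ndarray, ops: TissueOperators,
                       node_set: np.ndarray, region: str,
                       t: float) -> ActivationSummary:
    """Summary over a named global node set (tissue members only)."""
    loc = ops.glob2tis[np.asarray(node_set)]
    loc = loc[loc >= 0]
    return ActivationSummary(
        region=region, sample_time=t,
        fraction_activated=threshold_fraction(vm_tissue, loc, ACTIVATION_MV,
                                              "above"),
        fraction_hyperpolarised=threshold_fraction(vm_tissue, loc,
                                                   HYPERPOL_MV, "below"))


# ======================================================================
# filaments
# ======================================================================

@dataclass
class FilamentSet:
    """Connected filament loci at one instant."""

    count: int
    time: float
    cell_labels: np.ndarray = field(repr=False)  # (*dims) int component ids


def _nodal(grid: LabeledGrid, ops: TissueOperators, vm: np.ndarray) -> np.ndarray:
    full = np.full(grid.n_nodes, np.nan)
    full[ops.tissue_nodes] = vm
    return full.reshape(grid.node_shape)


def detect_filaments(vm_now: np.ndarray, vm_prev: np.ndarray, dt: float,
                     grid: LabeledGrid, ops: TissueOperators | None = None,
                     time: float = 0.0) -> FilamentSet:
    """Mark tissue cells crossed by both Vm = -20 mV and dVm/dt = 0.

    ``vm_now``/``vm_prev`` are consecutive tissue-node frames (or full
    nodal grids if ``ops`` is None); marked cells are linked by full
    vertex connectivity (26-connectivity in 3-D, 8 in 2-D): a filament
    crossing a cell obliquely marks diagonal neighbours, which face-only
    adjacency would fragment into spurious extra filaments.
    """
    if vm_now.shape != vm_prev.shape:
        raise ValueError("mismatched frames")
    if ops is not None:
        vm_now = _nodal(grid, ops, vm_now)
        vm_prev = _nodal(grid, ops, vm_prev)
    else:
        vm_now = vm_now.reshape(grid.node_shape)
        vm_prev = vm_prev.reshape(grid.node_shape)
    dvdt = (vm_now - vm_prev) / dt

    ndim = grid.ndim
    offs = list(np.ndindex(*(2,) * ndim))

    def corner_minmax(f):
        mn = np.full(grid.dims, np.inf)
        mx = np.full(grid.dims, -np.inf)
        for off in offs:
            sl = tuple(slice(o, o + n) for o, n in zip(off, grid.dims))
            mn = np.fmin(mn, f[sl])
            mx = np.fmax(mx, f[sl])
        return mn, mx

    vmn, vmx = corner_minmax(vm_now)
    dmn, dmx = corner_minmax(dvdt)
    marked = (vmn <= ACTIVATION_MV) & (vmx >= ACTIVATION_MV) \
        & (dmn <= 0.0) & (dmx >= 0.0) & grid.tissue_cells()
    structure = ndimage.generate_binary_structure(ndim, ndim)
    labels, count = ndimage.label(marked, structure=structure)
    return FilamentSet(count=int(count), time=time, cell_labels=labels)


def phase_singularities_2d(vm_now: np.ndarray, vm_prev: np.ndarray,
                           v_star: float = ACTIVATION_MV) -> list[tuple[int, int, int]]:
    """Phase-winding singularity detection on a 2-D nodal field.

    The phase is defined by time-delay embedding,
    ``theta = atan2(Vm(t) - V*, Vm(t-dt) - V*)``; a plaquette whose
    summed wrapped phase differences reach ±2π hosts a singularity.
    Returns ``(i, j, charge)`` per singular plaquette.
    """
    theta = np.arctan2(vm_now - v_star, vm_prev - v_star)

    def wrap(a):
        return (a + np.pi) % (2.0 * np.pi) - np.pi

    # plaquette corners: (i,j) -> (i+1,j) -> (i+1,j+1) -> (i,j+1) -> back
    d1 = wrap(theta[1:, :-1] - theta[:-1, :-1])
    d2 = wrap(theta[1:, 1:] - theta[1:, :-1])
    d3 = wrap(theta[:-1, 1:] - theta[1:, 1:])
    d4 = wrap(theta[:-1, :-1] - theta[:-1, 1:])
    winding = d1 + d2 + d3 + d4
    out = []
    for i, j in np.argwhere(np.abs(winding) > np.pi):
        out.append((int(i), int(j), int(np.sign(winding[i, j]))))
    return out


def count_phase_singularities(vm_now, vm_prev, v_star: float = ACTIVATION_MV) -> int:
    return len(phase_singularities_2d(vm_now, vm_prev, v_star))


# ======================================================================
# virtual-electrode polarity
# ======================================================================

def ve_polarity_summary(dvm: np.ndarray, ops: TissueOperators,
                        node_sets: dict[str, np.ndarray]) -> dict[str, dict]:
    """Signed ΔVm statistics per named surface node set.

    ``dvm`` is Vm(shock) − Vm(matched control) on tissue nodes; sets with
    no tissue members are reported as empty.
    """
    out = {}
    for name, nodes in node_sets.items():
        loc = ops.glob2tis[np.asarray(nodes, dtype=np.int64)] \
            if len(nodes) else np.array([], dtype=np.int64)
        loc = loc[loc >= 0]
        if loc.size == 0:
            out[name] = {"n": 0, "mean": np.nan, "min": np.nan, "max": np.nan}
            continue
        v = dvm[loc]
        out[name] = {"n": int(loc.size), "mean": float(v.mean()),
                     "min": float(v.min()), "max": float(v.max())}
    return out


# ======================================================================
# electrode circuit
# ======================================================================

def compute_resistance(ops: TissueOperators, state: SimState,
                       applied_mV: float, electrode_set: np.ndarray,
                       ground_set: np.ndarray,
                       conservation_tol: float = 1e-6) -> float:
    """Electrode-circuit resistance (Ω) from the discrete flux integral.

    The ground current is the sum of discrete boundary fluxes over the
    ground node set; it must balance the electrode-side current within
    ``conservation_tol`` (relative).  In 2-D the result is per unit depth
    (Ω·cm reported as Ω for a 1 cm extrusion).
    """
    i_el = ops.boundary_current(state, electrode_set)
    i_gnd = ops.boundary_current(state, ground_set)
    if abs(i_el) < 1e-12:
        raise ValueError("zero electrode current; no resistance defined")
    if abs(i_el + i_gnd) > conservation_tol * abs(i_el):
        raise ValueError(
            f"electrode/ground current mismatch: {i_el:.6g} vs {-i_gnd:.6g}")
    # mV / µA -> kΩ; report Ω
    return float(abs(applied_mV / i_el) * 1000.0)


def shock_energy(voltage: float, duration_ms: float, resistance: float) -> float:
    """Energy (J) of a square monophasic pulse: V²·T/R with T in seconds."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    return voltage ** 2 * (duration_ms / 1000.0) / resistance


def shock_energy_waveform(t_ms: np.ndarray, v_volts: np.ndarray,
                          resistance: float) -> float:
    """Trapezoid-rule energy (J) for an arbitrary voltage waveform."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    return float(np.trapezoid(np.asarray(v_volts) ** 2,
                              np.asarray(t_ms) / 1000.0) / resistance)


def field_strength_fraction(phie: np.ndarray, ops: TissueOperators,
                            threshold_v_per_cm: float) -> float:
    """% of tissue cells with |grad phi_e| above threshold (V/cm).

    The field is piecewise constant per cell, from the Q1 gradient of the
    nodal extracellular potential at the cell centre.
    """
    from .fibers import _cell_mean_and_grad

    grid = ops.grid
    full = np.full(grid.n_nodes, np.nan)
    full[ops.active_nodes] = phie
    tissue = grid.tissue_cells()
    _, grad = _cell_mean_and_grad(grid, full, tissue)  # mV/cm
    mag = np.linalg.norm(grad, axis=1) / 1000.0        # V/cm
    return 100.0 * float(np.count_nonzero(mag > threshold_v_per_cm)) / mag.size
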