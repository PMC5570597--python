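"""Experimental protocols: uniform pacing with coupling-interval
checkpoints, monophasic shock delivery of either polarity, reentry
induction and shocks during reentry.

The pacing protocol stimulates every tissue node uniformly (5 beats at a
500 ms cycle length by default) so that the tissue state at a coupling
interval (CI) is spatially uniform; shocks are then applied between an
intracavitary electrode and the grounded outer boundary by switching to
the bidomain representation with Dirichlet extracellular potentials.
Anodal polarity puts the cavity electrode at +V, cathodal at -V; ground
stays at 0.  "Shock-end" is sampled at 9 ms and "post-shock" at 20 ms
after shock onset for a 10 ms pulse, matching the standard figure
annotations for this protocol family.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np

from .solver import (DirichletBC, SimState, Stimulus, StimulusSet,
                     TissueOperators)
from .analysis import count_phase_singularities, detect_filaments, _nodal
from . import units


# ======================================================================
# specs
# ======================================================================

@dataclass
class PacingSpec:
    """Uniform transmembrane pacing with CI checkpoints.

    ``strength`` is a volume current density (µA/cm³); the per-membrane
    current is strength/beta.  The default (42 mA/cm³ -> 30 µA/cm²) is a
    standard suprathreshold amplitude for a 2 ms pulse.
    """

    n_beats: int = 5
    bcl: float = 500.0
    strength: float = 42000.0
    duration: float = 2.0
    cis: tuple[float, ...] = (220.0, 240.0, 280.0, 320.0, 340.0)

    def __post_init__(self):
        if max(self.cis) > self.bcl:
            raise ValueError("coupling interval exceeds the basic cycle length")


@dataclass
class ShockSpec:
    """Monophasic square shock between electrode and ground node sets."""

    voltage: float                 # applied |V| in volts
    polarity: str = "anodal"       # anodal: electrode +V; cathodal: -V
    duration: float = 10.0         # ms
    electrode: np.ndarray = dc_field(default_factory=lambda: np.array([], int))
    ground: np.ndarray = dc_field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        if self.voltage < 0:
            raise ValueError("voltage must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.polarity not in ("anodal", "cathodal"):
            raise ValueError("polarity must be 'anodal' or 'cathodal'")
        if np.intersect1d(self.electrode, self.ground).size:
            raise ValueError("electrode and ground node sets overlap")

    @property
    def electrode_mv(self) -> float:
        sign = 1.0 if self.polarity == "anodal" else -1.0
        return sign * self.voltage * units.V_TO_MV

    @classmethod
    def for_grid(cls, grid, voltage: float, polarity: str = "anodal",
                 duration: float = 10.0) -> "ShockSpec":
        return cls(voltage=voltage, polarity=polarity, duration=duration,
                   electrode=grid.node_sets["electrode_nodes"],
                   ground=grid.node_sets["ground_boundary"])


# ======================================================================
# pacing / checkpointing
# ======================================================================

def precondition_and_checkpoint(ops: TissueOperators, model,
                                pacing: PacingSpec,
                                uniform_fast_path: bool = True,
                                dt: float = 0.02,
                                equilibrate_ms: float = 2000.0,
                                eq_state=None,
                                ) -> dict[float, SimState]:
    """Equilibrate, pace uniformly, checkpoint at each coupling interval.

    By symmetry a uniform monodomain tissue under a uniform transmembrane
    stimulus stays exactly uniform and equal to the single cell, so the
    default fast path integrates one cell and broadcasts; set
    ``uniform_fast_path=False`` to integrate the full tissue (used by the
    tests that verify the equivalence).
    """
    from .membrane import paced_checkpoints

    stim_area = pacing.strength / ops.beta
    if uniform_fast_path:
        _, cps = paced_checkpoints(
            model, n_beats=pacing.n_beats, bcl=pacing.bcl,
            stim_duration=pacing.duration, stim_amp=stim_area,
            cis=list(pacing.cis), dt=dt, equilibrate_ms=equilibrate_ms,
            eq_state=eq_state)
        out = {}
        for ci, (vm, st) in cps.items():
            out[ci] = SimState(
                vm=np.full(ops.n_t, vm),
                phie=np.zeros(ops.n_a),
                membrane={k: np.full(ops.n_t, float(np.asarray(v).ravel()[0]))
                          for k, v in st.items()},
                t=0.0)
        return out

    # full-tissue path
    state = ops.initial_state(model)
    # quiescent equilibration (uniform: cheap accuracy not an issue)
    ops.run(model, state, equilibrate_ms, dt, mode="monodomain")
    stims = StimulusSet(transmembrane=[
        Stimulus(strength=pacing.strength, t0=state.t + k * pacing.bcl,
                 t1=state.t + k * pacing.bcl + pacing.duration)
        for k in range(pacing.n_beats)])
    last = state.t + (pacing.n_beats - 1) * pacing.bcl
    out = {}
    targets = sorted(pacing.cis)
    for ci in targets:
        t_target = last + ci
        ops.run(model, state, t_target - state.t, dt, stimuli=stims,
                mode="monodomain")
        snap = state.copy()
        snap.t = 0.0
        out[ci] = snap
    return out


# ======================================================================
# shock application
# ======================================================================

@dataclass
class ShockRun:
    """Recorded shock experiment: Vm samples and matched control."""

    shock: ShockSpec
    sample_times: tuple[float, ...]
    samples: dict[float, np.ndarray]          # t (ms from onset) -> Vm
    control: dict[float, np.ndarray]
    phie_shock_end: np.ndarray
    movie: list[tuple[float, np.ndarray]] = dc_field(default_factory=list)

    def dvm(self, t: float) -> np.ndarray:
        return self.samples[t] - self.control[t]


def _run_windowed(ops, model, state, shock: Optional[ShockSpec],
                  until: float, dt_shock: float, dt_post: float,
                  sample_times: Sequence[float], movie_every: Optional[float],
                  phases_out: dict):
    """Advance through shock window then post window, sampling Vm."""
    bcs = [DirichletBC(shock.ground, 0.0, 0.0, np.inf)] if shock is not None \
        else []
    if shock is not None and shock.voltage > 0:
        bcs.append(DirichletBC(shock.electrode, shock.electrode_mv,
                               0.0, shock.duration))
    stimuli = StimulusSet(dirichlet=bcs)
    samples = {}
    movie = []
    t_shock_end = shock.duration if shock is not None else 0.0
    phie_end = None
    targets = sorted(sample_times)
    eps = 1e-9

    while state.t < until - eps:
        dt = dt_shock if state.t < t_shock_end - eps else dt_post
        # land exactly on sample times and the shock/post boundary
        next_stop = until
        for tt in targets + [t_shock_end]:
            if state.t + eps < tt < next_stop:
                next_stop = tt
        dt = min(dt, next_stop - state.t)
        ops.step_bidomain(model, state, dt, dt, stimuli)
        for tt in targets:
            if abs(state.t - tt) < 1e-6 and tt not in samples:
                samples[tt] = state.vm.copy()
        if abs(state.t - t_shock_end) < 1e-6 and phie_end is None:
            phie_end = state.phie.copy()
        if movie_every is not None:
            if not movie or state.t - movie[-1][0] >= movie_every - 1e-6:
                movie.append((state.t, state.vm.copy()))
    phases_out["samples"] = samples
    phases_out["movie"] = movie
    phases_out["phie_end"] = phie_end if phie_end is not None \
        else state.phie.copy()
    return state


def apply_shock(ops: TissueOperators, model, checkpoint: SimState,
                shock: ShockSpec, post_window: float = 10.0,
                sample_times: Sequence[float] = (9.0, 20.0),
                dt_shock: float = 0.005, dt_post: float = 0.02,
                control: bool = True,
                movie_every: Optional[float] = None) -> ShockRun:
    """Deliver a monophasic shock from a checkpoint and record the response.

    The run switches to the bidomain representation, clamps the electrode
    at ±V for the shock duration, then floats the electrode (ground stays
    clamped) for ``post_window`` ms.  A matched control continues from the
    same checkpoint with the electrode floating throughout, so that
    ΔVm = Vm(shock) − Vm(control) isolates the shock effect.
    """
    if np.intersect1d(shock.electrode, shock.ground).size:
        raise ValueError("electrode and ground node sets overlap")
    until = shock.duration + post_window
    sample_times = tuple(t for t in sample_times if t <= until + 1e-9)

    state = checkpoint.copy()
    state.t = 0.0
    rec: dict = {}
    _run_windowed(ops, model, state, shock, until, dt_shock, dt_post,
                  sample_times, movie_every, rec)

    ctrl_rec: dict = {"samples": {}, "movie": []}
    if control:
        cstate = checkpoint.copy()
        cstate.t = 0.0
        null = ShockSpec(voltage=0.0, polarity=shock.polarity,
                         duration=shock.duration, electrode=shock.electrode,
                         ground=shock.ground)
        _run_windowed(ops, model, cstate, null, until, dt_shock, dt_post,
                      sample_times, movie_every, ctrl_rec)

    return ShockRun(shock=shock, sample_times=sample_times,
                    samples=rec["samples"], control=ctrl_rec["samples"],
                    phie_shock_end=rec["phie_end"], movie=rec["movie"])


# ======================================================================
# reentry
# ======================================================================

class ReentryFailure(RuntimeError):
    pass


def induce_reentry(ops: TissueOperators, model, s1_nodes: np.ndarray,
                   s2_nodes: np.ndarray,
                   s2_timings: Sequence[float],
                   s1_strength: float = 70000.0,
                   s2_strength: float = 70000.0,
                   stim_duration: float = 2.0,
                   follow_ms: float = 350.0,
                   settle_ms: float = 50.0,
                   dt: float = 0.02, dt_pde: Optional[float] = None,
                   min_rotations: int = 3,
                   period_hint: float = 120.0) -> tuple[SimState, dict]:
    """Cross-field S1-S2 reentry induction with an S2 timing scan.

    An S1 wave is launched from ``s1_nodes``; at each candidate S2 time a
    branch applies the S2 stimulus over ``s2_nodes`` (the classic
    cross-field quadrant) and the branch is followed for ``follow_ms``.
    Success requires sustained activity with at least one phase
    singularity present through ``min_rotations`` rotation periods
    (``period_hint`` each).  Returns the first successful branch advanced
    ``settle_ms`` past the check, plus diagnostics.
    """
    dt_pde = dt if dt_pde is None else dt_pde
    timings = sorted(s2_timings)
    base = ops.initial_state(model)
    stim_s1 = StimulusSet(transmembrane=[
        Stimulus(strength=s1_strength, t0=0.0, t1=stim_duration,
                 nodes=s1_nodes)])

    grid = ops.grid
    check_window = max(min_rotations * period_hint, 150.0)

    tried = []
    for t2 in timings:
        ops.run(model, base, t2 - base.t, dt, dt_pde, stimuli=stim_s1,
                mode="monodomain")
        branch = base.copy()
        bmodel = copy.deepcopy(model)
        stim_s2 = StimulusSet(transmembrane=[
            Stimulus(strength=s2_strength, t0=branch.t,
                     t1=branch.t + stim_duration, nodes=s2_nodes)])
        ops.run(bmodel, branch, stim_duration + 1.0, dt, dt_pde,
                stimuli=stim_s2, mode="monodomain")
        ops.run(bmodel, branch, follow_ms - check_window, dt, dt_pde,
                mode="monodomain")

        # sample PS presence across the check window
        ok = True
        n_checks = max(4, min_rotations + 1)
        ps_counts = []
        for _ in range(n_checks):
            prev = branch.vm.copy()
            ops.run(bmodel, branch, 1.0, dt, dt_pde, mode="monodomain")
            if grid.ndim == 2:
                now_n = np.nan_to_num(_nodal(grid, ops, branch.vm), nan=-85.0)
                prev_n = np.nan_to_num(_nodal(grid, ops, prev), nan=-85.0)
                cnt = count_phase_singularities(now_n, prev_n)
            else:
                cnt = detect_filaments(branch.vm, prev, 1.0, grid, ops).count
            ps_counts.append(cnt)
            if cnt < 1 or float(branch.vm.max()) < -40.0:
                ok = False
                break
            ops.run(bmodel, branch, check_window / n_checks - 1.0, dt, dt_pde,
                    mode="monodomain")
        tried.append((t2, ps_counts, ok))
        if ok:
            ops.run(bmodel, branch, settle_ms, dt, dt_pde, mode="monodomain")
            return branch, {"s2_time": t2, "ps_counts": ps_counts,
                            "scanned": tried}
    raise ReentryFailure(
        f"no sustained reentry for S2 timings {list(timings)}; "
        f"diagnostics: {tried}")


# ======================================================================
# shocks during VT
# ======================================================================

def shock_during_vt(ops: TissueOperators, model, vt_state: SimState,
                    shock: ShockSpec, phases: Sequence[float],
                    post_window: float = 90.0, stride: float = 5.0,
                    dt: float = 0.02, dt_shock: float = 0.005,
                    ) -> dict[float, list[tuple[float, int]]]:
    """Apply the shock at several instants of an ongoing arrhythmia.

    For each phase offset the arrhythmia is advanced (monodomain), the
    shock delivered (bidomain, electrode clamped for its duration), and
    filaments counted every ``stride`` ms over the post-shock window.
    Returns ``{phase: [(t_ms_after_shock_end, filament_count), ...]}``.
    """
    grid = ops.grid
    out: dict[float, list[tuple[float, int]]] = {}
    base = vt_state.copy()
    bmodel = copy.deepcopy(model)
    t0 = base.t
    for phase in sorted(phases):
        ops.run(bmodel, base, (t0 + phase) - base.t, dt, mode="monodomain")
        branch = base.copy()
        pmodel = copy.deepcopy(bmodel)
        bcs = [DirichletBC(shock.ground, 0.0, branch.t, np.inf)]
        if shock.voltage > 0:
            bcs.append(DirichletBC(shock.electrode, shock.electrode_mv,
                                   branch.t, branch.t + shock.duration))
        stimuli = StimulusSet(dirichlet=bcs)
        n_shock = int(round(shock.duration / dt_shock))
        for _ in range(n_shock):
            ops.step_bidomain(pmodel, branch, dt_shock, dt_shock, stimuli)

        series = []
        t_end = branch.t
        n_samples = int(round(post_window / stride))
        for k in range(n_samples):
            target = t_end + (k + 1) * stride
            ops.run(pmodel, branch, (target - 1.0) - branch.t, dt,
                    mode="monodomain")
            prev = branch.vm.copy()
            ops.run(pmodel, branch, 1.0, dt, mode="monodomain")
            fs = detect_filaments(branch.vm, prev, 1.0, grid, ops,
                                  time=branch.t - t_end)
            series.append((round(branch.t - t_end, 6), fs.count))
        out[phase] = series
    return out
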