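"""Single-cell runners: equilibration, paced traces, APD measurement.

A spatially uniform tissue under a uniform transmembrane stimulus has no
diffusive currents, so the paced single cell is the exact solution of the
uniform-pacing tissue protocol; these runners provide both the pacing
preconditioner's fast path and the oracle it is tested against.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np


@dataclass
class SingleCellTrace:
    t: np.ndarray
    vm: np.ndarray
    extras: dict

    def vm_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.vm))


def _clone(state: dict) -> dict:
    return {k: np.array(v, copy=True) for k, v in state.items()}


def run_single_cell(model, duration: float, dt: float = 0.02,
                    stim_times: list[float] | None = None,
                    stim_duration: float = 2.0, stim_amp: float = 30.0,
                    vm0: float | None = None, state0: dict | None = None,
                    record_dt: float = 0.5,
                    snapshot_times: list[float] | None = None,
                    record_keys: tuple[str, ...] = ()) -> SingleCellTrace:
    """Forward-integrate one cell; stim_amp in µA/cm² (depolarising).

    ``snapshot_times`` collects deep-copied ``(vm, state)`` pairs in
    ``extras['snapshots']`` keyed by time.
    """
    stim_times = sorted(stim_times or [])
    vm = np.array([model.initial_vm(1)[0] if vm0 is None else vm0])
    state = model.initial_state(1) if state0 is None else _clone(state0)
    cm = getattr(getattr(model, "params", None), "Cm", 1.0)

    n_steps = int(round(duration / dt))
    every = max(1, int(round(record_dt / dt)))
    ts, vs = [], []
    rec = {k: [] for k in record_keys}
    snaps = {}
    snap_steps = {int(round(s / dt)): s for s in (snapshot_times or [])}

    for i in range(n_steps + 1):
        t = i * dt
        if i % every == 0:
            ts.append(t)
            vs.append(vm[0])
            for k in record_keys:
                rec[k].append(float(np.asarray(state[k]).ravel()[0]))
        if i in snap_steps:
            snaps[snap_steps[i]] = (float(vm[0]), _clone(state))
        if i == n_steps:
            break
        stim = 0.0
        for t0 in stim_times:
            if t0 <= t < t0 + stim_duration:
                stim = stim_amp
                break
        i_ion = model.step(vm, state, dt, stim=stim)
        vm = vm + dt * (-i_ion + stim) / cm

    extras = {"state": state, "vm_end": float(vm[0]), "snapshots": snaps}
    extras.update({k: np.array(v) for k, v in rec.items()})
    return SingleCellTrace(t=np.array(ts), vm=np.array(vs), extras=extras)


def equilibrate(model, duration: float = 2000.0, dt: float = 0.02):
    """Quiescent equilibration; returns (vm, state) at the end."""
    tr = run_single_cell(model, duration, dt=dt, stim_times=[], record_dt=50.0)
    return tr.extras["vm_end"], tr.extras["state"]


def paced_checkpoints(model, n_beats: int = 5, bcl: float = 500.0,
                      stim_duration: float = 2.0, stim_amp: float = 30.0,
                      cis: list[float] = (220.0,), dt: float = 0.02,
                      equilibrate_ms: float = 2000.0, eq_state=None):
    """Equilibrate, pace ``n_beats`` at ``bcl``, snapshot at each CI.

    Coupling intervals are measured from the onset of the final stimulus.
    Returns ``(trace, {ci: (vm, state)})``; the trace covers the pacing
    train so the last-beat time course can be inspected directly.
    ``eq_state`` (a ``(vm, state)`` pair) skips the quiescent
    equilibration when an equilibrated state is already at hand.
    """
    if max(cis) > bcl:
        raise ValueError("coupling interval exceeds the basic cycle length")
    if eq_state is not None:
        vm0, state0 = eq_state
    else:
        vm0, state0 = equilibrate(model, duration=equilibrate_ms, dt=dt)
    stim_times = [k * bcl for k in range(n_beats)]
    last = stim_times[-1]
    duration = last + max(cis) + 1.0
    tr = run_single_cell(model, duration, dt=dt, stim_times=stim_times,
                         stim_duration=stim_duration, stim_amp=stim_amp,
                         vm0=vm0, state0=state0, record_dt=0.5,
                         snapshot_times=[last + ci for ci in cis])
    checkpoints = {}
    for ci in cis:
        vm, st = tr.extras["snapshots"][last + ci]
        checkpoints[ci] = (vm, copy.deepcopy(st))
    return tr, checkpoints


def apd90(t: np.ndarray, vm: np.ndarray, t_stim: float = 0.0) -> float:
    """Action-potential duration at 90% repolarisation after ``t_stim``."""
    sel = t >= t_stim
    t, vm = t[sel], vm[sel]
    v_rest = vm[0]
    i_peak = int(np.argmax(vm))
    v_peak = vm[i_peak]
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.flatnonzero(vm[i_peak:] <= v90)
    if below.size == 0:
        return float("nan")
    j = i_peak + below[0]
    # linear interpolation across the crossing
    t_cross = np.interp(v90, [vm[j], vm[j - 1]], [t[j], t[j - 1]])
    return float(t_cross - t[0])
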