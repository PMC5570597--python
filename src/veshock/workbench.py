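"""Run configuration, experiment presets and the pipeline driver.

A ``RunConfig`` fully determines a reproducible experiment: geometry,
membrane, conductivities, protocol and outputs.  ``preset_experiment``
returns desk-scale configurations mirroring the canonical experiment
designs (VE polarity at a detached trabecula, strength/CI sweeps,
polarity comparison, shocks during reentry, the shock-energy table);
``run`` executes one and writes a run directory with the resolved
config, a manifest and CSV/JSON summaries.

Seeds only randomise optional geometry placement; the physics is
deterministic.
"""
from __future__ import annotations

import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import io
from .analysis import (shock_energy, threshold_fraction, ve_polarity_summary,
                       compute_resistance)
from .fibers import assign_fibers_rule_based
from .grid import (AnnulusConfig, SlabConfig, build_annulus_cavity,
                   build_slab_with_trabecula)
from .membrane import make_model
from .protocols import (PacingSpec, ShockSpec, apply_shock, induce_reentry,
                        precondition_and_checkpoint, shock_during_vt)
from .solver import ConductivitySet, TissueOperators


# ======================================================================
# config models
# ======================================================================

class GeometryConfig(BaseModel):
    kind: Literal["slab", "annulus"] = "slab"
    nx: int = 72
    nz: int = 0
    spacing_um: float = 250.0
    wall: int = 40
    trabecula: Literal["none", "attached", "detached"] = "detached"
    trab_length: int = 20
    trab_thickness: int = 3
    cleft: int = 2
    n_trabeculae: int = 1
    electrode_offset: int = 4
    seed: Optional[int] = None

    def build(self):
        if self.kind == "slab":
            return build_slab_with_trabecula(SlabConfig(
                nx=self.nx, nz=self.nz, spacing_um=self.spacing_um,
                wall=self.wall, trabecula=self.trabecula,
                trab_length=self.trab_length,
                trab_thickness=self.trab_thickness, cleft=self.cleft,
                n_trabeculae=self.n_trabeculae,
                electrode_offset=self.electrode_offset, seed=self.seed))
        return build_annulus_cavity(AnnulusConfig(
            n=self.nx, spacing_um=self.spacing_um,
            n_trabeculae=self.n_trabeculae, seed=self.seed))


class MembraneConfig(BaseModel):
    model: str = "human_ventricular_2004"
    electroporation: bool = True
    k_current: bool = True
    scales: dict[str, float] = Field(default_factory=dict)

    def build(self):
        from .membrane import MembraneParams
        return make_model(self.model, params=MembraneParams(
            electroporation=self.electroporation, k_current=self.k_current,
            scales=dict(self.scales)))


class SolverConfig(BaseModel):
    sigma_i: tuple[float, float] = (0.174, 0.0193)
    sigma_e: tuple[float, float] = (0.625, 0.236)
    sigma_b: float = 1.0
    scale: float = 0.5625          # CV-reduction calibration result
    dt_ode: float = 0.02
    dt_shock: float = 0.005

    def conductivities(self) -> ConductivitySet:
        return ConductivitySet(sigma_i=self.sigma_i, sigma_e=self.sigma_e,
                               sigma_b=self.sigma_b, scale=self.scale)


class ProtocolConfig(BaseModel):
    kind: Literal["energy_table", "trabecula_ve", "ss_ci_sweep",
                  "polarity_sweep", "vt_shocks"] = "trabecula_ve"
    voltages: list[float] = [5.0]
    polarities: list[str] = ["anodal", "cathodal"]
    cis: list[float] = [280.0]
    shock_duration: float = 10.0
    post_window: float = 10.0
    resistance_ohm: float = 36.4   # energy table circuit resistance
    phases: list[float] = [0.0, 50.0, 100.0, 150.0]
    vt_post_window: float = 90.0
    pacing: dict = Field(default_factory=dict)

    @field_validator("polarities")
    @classmethod
    def _pol(cls, v):
        for p in v:
            if p not in ("anodal", "cathodal"):
                raise ValueError(f"bad polarity {p!r}")
        return v


class OutputConfig(BaseModel):
    stride_ms: float = 1.0
    write_vtk: bool = False


class RunConfig(BaseModel):
    name: str = "run"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    membrane: MembraneConfig = Field(default_factory=MembraneConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0

    def content_hash(self) -> str:
        return io.dict_hash(self.model_dump())


class RunRecord(BaseModel):
    run_dir: str
    config_hash: str
    manifest: list[str]
    log: list[str]
    summary: dict


def load_config(path) -> RunConfig:
    """Read and schema-validate a RunConfig from YAML or JSON."""
    import yaml

    with open(path) as f:
        data = yaml.safe_load(f)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(config.model_dump(), f, sort_keys=True)


# ======================================================================
# presets
# ======================================================================

PRESETS = ("fig2_trabecula_ve", "fig6_ss_ci_sweep", "fig8_polarity_sweep",
           "fig9_vt_shocks", "energy_table")


def preset_experiment(name: str, smoke: bool = False, seed: int = 0) -> RunConfig:
    """Desk-scale configuration for a named canonical experiment.

    ``smoke=True`` shrinks grids and windows to pipeline-validation size.
    """
    if name == "energy_table":
        return RunConfig(name=name, protocol=ProtocolConfig(
            kind="energy_table", voltages=[1.0, 3.0, 5.0, 10.0],
            resistance_ohm=36.4, shock_duration=10.0), seed=seed)

    if name == "fig2_trabecula_ve":
        geo = GeometryConfig()
        proto = ProtocolConfig(kind="trabecula_ve", voltages=[5.0],
                               cis=[280.0], post_window=10.0)
        if smoke:
            geo = GeometryConfig(nx=40, wall=10, trab_length=10, cleft=2,
                                 trab_thickness=2, electrode_offset=2)
            proto.post_window = 1.0
        return RunConfig(name=name, geometry=geo, protocol=proto, seed=seed)

    if name == "fig6_ss_ci_sweep":
        proto = ProtocolConfig(kind="ss_ci_sweep",
                               voltages=[1.0, 3.0, 5.0, 10.0],
                               polarities=["anodal"],
                               cis=[240.0, 280.0, 320.0, 340.0])
        geo = GeometryConfig()
        if smoke:
            geo = GeometryConfig(nx=40, wall=10, trab_length=10,
                                 trab_thickness=2, electrode_offset=2)
            proto.voltages = [5.0]
            proto.cis = [340.0]
        return RunConfig(name=name, geometry=geo, protocol=proto, seed=seed)

    if name == "fig8_polarity_sweep":
        proto = ProtocolConfig(kind="polarity_sweep", voltages=[10.0],
                               cis=[240.0, 280.0, 320.0, 340.0])
        geo = GeometryConfig()
        if smoke:
            geo = GeometryConfig(nx=40, wall=10, trab_length=10,
                                 trab_thickness=2, electrode_offset=2)
            proto.cis = [340.0]
        return RunConfig(name=name, geometry=geo, protocol=proto, seed=seed)

    if name == "fig9_vt_shocks":
        # Desk-scale arrhythmia preset: 2.4 cm square wall hosting a
        # functional rotor.  Isotropic conductivities (cross-fibre
        # conduction blocks on the coarse reentry lattice otherwise),
        # accelerated repolarisation to fit the wavelength, 0.05 ms ODE
        # step; see docs/methods.md.
        geo = GeometryConfig(nx=48, nz=1, spacing_um=500.0, wall=48,
                             trabecula="detached", trab_length=10,
                             trab_thickness=2, cleft=1, n_trabeculae=2,
                             electrode_offset=2, seed=seed)
        mem = MembraneConfig(scales={"g_kr": 12.0, "g_ks": 12.0,
                                     "g_cal": 1.0})
        sol = SolverConfig(sigma_i=(0.174, 0.174), sigma_e=(0.625, 0.625),
                           scale=0.25, dt_ode=0.05)
        proto = ProtocolConfig(kind="vt_shocks", voltages=[10.0],
                               phases=[0.0, 50.0, 100.0, 150.0],
                               vt_post_window=90.0)
        if smoke:
            proto.phases = [0.0]
            proto.vt_post_window = 20.0
        return RunConfig(name=name, geometry=geo, membrane=mem, solver=sol,
                         protocol=proto, seed=seed)

    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


# ======================================================================
# driver
# ======================================================================

def run(config: RunConfig, out_dir) -> RunRecord:
    """Execute a configured experiment and write its run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    manifest: list[str] = []
    t_start = time.time()

    def note(msg: str):
        log.append(f"[{time.time() - t_start:8.1f}s] {msg}")

    def write(name: str, writer, *a):
        p = writer(out / name, *a)
        manifest.append(name)
        return p

    cfg_dict = config.model_dump()
    write("config.json", io.write_json, cfg_dict)
    note(f"config hash {config.content_hash()[:12]}")

    kind = config.protocol.kind
    summary: dict = {"kind": kind}
    try:
        _execute(config, out, note, manifest, summary)
    except Exception as exc:
        note(f"ABORTED in stage {kind!r}: {exc!r}")
        (out / "log.txt").write_text("\n".join(log) + "\n")
        raise

    write("summary.json", io.write_json, summary)
    write("log.txt", lambda p: (Path(p).write_text("\n".join(log) + "\n"),
                                p)[1])
    return RunRecord(run_dir=str(out), config_hash=config.content_hash(),
                     manifest=sorted(manifest), log=log, summary=summary)


def _execute(config: RunConfig, out: Path, note, manifest, summary: dict):
    kind = config.protocol.kind
    if kind == "energy_table":
        rows = [{"voltage_V": v,
                 "duration_ms": config.protocol.shock_duration,
                 "resistance_ohm": config.protocol.resistance_ohm,
                 "energy_J": shock_energy(v, config.protocol.shock_duration,
                                          config.protocol.resistance_ohm)}
                for v in config.protocol.voltages]
        io.write_csv(out / "energies.csv", rows)
        manifest.append("energies.csv")
        summary["energies_J"] = {str(r["voltage_V"]): r["energy_J"]
                                 for r in rows}
    else:
        summary.update(_run_tissue(config, out, note, manifest))


def _run_tissue(config: RunConfig, out: Path, note, manifest) -> dict:
    proto = config.protocol
    note("building geometry")
    grid = config.geometry.build()
    fibers = assign_fibers_rule_based(grid)
    conds = config.solver.conductivities()
    ops = TissueOperators(grid, fibers, conds)
    model = config.membrane.build()
    note(f"grid {grid.dims}, {ops.n_t} tissue nodes")

    if proto.kind == "vt_shocks":
        return _run_vt(config, grid, ops, model, out, note, manifest)

    pacing_kwargs = dict(proto.pacing)
    equilibrate_ms = pacing_kwargs.pop("equilibrate_ms", 2000.0)
    pacing = PacingSpec(cis=tuple(proto.cis), **pacing_kwargs)
    note(f"pacing {pacing.n_beats}x{pacing.bcl} ms, CIs {proto.cis}")
    cps = precondition_and_checkpoint(ops, model, pacing,
                                      equilibrate_ms=equilibrate_ms)

    rows = []
    pol_rows = []
    endo = grid.node_sets["endocardium"]
    loc_endo = ops.glob2tis[endo]
    loc_endo = loc_endo[loc_endo >= 0]
    surf_sets = {k: grid.node_sets[k] for k in
                 ("endocardium", "epicardium", "trabecula_proximal_face",
                  "trabecula_distal_face")}
    for ci in proto.cis:
        for v in proto.voltages:
            for pol in proto.polarities:
                note(f"shock CI={ci} V={v} {pol}")
                runrec = apply_shock(
                    ops, model, cps[ci],
                    ShockSpec.for_grid(grid, v, pol,
                                       duration=proto.shock_duration),
                    post_window=proto.post_window)
                row = {"ci_ms": ci, "voltage_V": v, "polarity": pol}
                for t, vm in sorted(runrec.samples.items()):
                    row[f"endo_activated_pct_{t:g}ms"] = threshold_fraction(
                        vm, loc_endo, -20.0, "above")
                    row[f"endo_hyperpol_pct_{t:g}ms"] = threshold_fraction(
                        vm, loc_endo, -80.0, "below")
                    row[f"tissue_activated_pct_{t:g}ms"] = threshold_fraction(
                        vm, np.arange(ops.n_t), -20.0, "above")
                rows.append(row)
                t9 = min(runrec.samples, key=lambda t: abs(t - 9.0))
                pol_sum = ve_polarity_summary(runrec.dvm(t9), ops, surf_sets)
                for surf, st in pol_sum.items():
                    pol_rows.append({"ci_ms": ci, "voltage_V": v,
                                     "polarity": pol, "surface": surf,
                                     "t_ms": t9, **st})
    io.write_csv(out / "activation.csv", rows)
    manifest.append("activation.csv")
    io.write_csv(out / "ve_polarity.csv", pol_rows)
    manifest.append("ve_polarity.csv")
    return {"n_shocks": len(rows),
            "activation": rows, "ve_polarity": pol_rows}


def _run_vt(config: RunConfig, grid, ops, model, out: Path, note,
            manifest) -> dict:
    proto = config.protocol
    ns = grid.node_shape
    idx = np.indices(ns)
    tmask = np.zeros(grid.n_nodes, dtype=bool)
    tmask[ops.tissue_nodes] = True
    s1 = np.flatnonzero((idx[0] < 4).ravel() & tmask)
    s2 = np.flatnonzero(((idx[0] < ns[0] // 2) & (idx[1] < ns[1] // 2)).ravel()
                        & tmask)
    note("inducing reentry (S2 scan)")
    dt = config.solver.dt_ode
    vt_state, info = induce_reentry(
        ops, model, s1, s2,
        s2_timings=np.arange(105.0, 200.0, 15.0),
        follow_ms=450.0, period_hint=140.0, dt=dt)
    note(f"reentry established: S2 at {info['s2_time']} ms")

    series = {}
    for pol in proto.polarities:
        shock = ShockSpec.for_grid(grid, proto.voltages[0], pol,
                                   duration=proto.shock_duration)
        note(f"VT shocks, {pol}")
        series[pol] = shock_during_vt(ops, model, vt_state, shock,
                                      phases=proto.phases,
                                      post_window=proto.vt_post_window,
                                      dt=dt,
                                      dt_shock=config.solver.dt_shock)
    rows = []
    for pol, per_phase in series.items():
        for phase, counts in per_phase.items():
            for t, c in counts:
                rows.append({"polarity": pol, "phase_ms": phase,
                             "t_post_ms": t, "filaments": c})
    io.write_csv(out / "filaments.csv", rows)
    manifest.append("filaments.csv")

    paired = []
    if {"anodal", "cathodal"} <= set(series):
        for phase in proto.phases:
            a = np.mean([c for _, c in series["anodal"][phase]])
            c = np.mean([c for _, c in series["cathodal"][phase]])
            paired.append({"phase_ms": phase, "anodal_mean": float(a),
                           "cathodal_mean": float(c),
                           "paired_diff": float(a - c)})
        io.write_csv(out / "paired_differences.csv", paired)
        manifest.append("paired_differences.csv")
    return {"s2_time": info["s2_time"], "paired_differences": paired}
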