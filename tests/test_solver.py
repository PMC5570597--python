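"""Tissue solvers: tensors, elliptic accuracy, conservation, cable
physics, model reductions, CV calibration."""
import numpy as np
import pytest

from conftest import tissue_sheet
from veshock.fibers import FiberField, assign_fibers_rule_based
from veshock.grid import Label, LabeledGrid, build_strand
from veshock.membrane import PassiveMembrane, make_model
from veshock.solver import (ConductivitySet, DirichletBC, SimState,
                            StabilityError, Stimulus, StimulusSet,
                            TissueOperators, assemble_tensors,
                            calibrate_cv_scale, fiber_tensors, measure_cv)


# ----------------------------------------------------------------- tensors
class TestTensors:
    def test_fibre_along_x_gives_diagonal_tensor(self):
        v = np.array([[1.0, 0.0]])
        t = fiber_tensors(v, 1.74, 0.193)  # mS/cm values of the defaults
        assert np.allclose(t[0], np.diag([1.74, 0.193]))

    def test_harmonic_mean_values(self):
        c = ConductivitySet()
        sm_l, sm_t = c.sm_ms_cm()
        # harmonic mean of (0.174, 0.625) and (0.0193, 0.236) S/m, in mS/cm
        assert sm_l == pytest.approx(10 * 0.174 * 0.625 / (0.174 + 0.625),
                                     rel=1e-12)
        assert sm_l == pytest.approx(1.3611, abs=2e-4)
        assert sm_t == pytest.approx(0.17841, abs=2e-4)

    def test_isotropic_tensor_rotation_invariant(self):
        rng = np.random.default_rng(0)
        vs = rng.normal(size=(50, 3))
        vs /= np.linalg.norm(vs, axis=1, keepdims=True)
        t = fiber_tensors(vs, 0.7, 0.7)
        assert np.abs(t - 0.7 * np.eye(3)).max() < 1e-12

    def test_scale_multiplies_tissue_not_bath(self):
        c = ConductivitySet(scale=0.25)
        assert c.si_ms_cm()[0] == pytest.approx(0.25 * 1.74)
        assert c.sb_ms_cm() == pytest.approx(10.0)

    def test_missing_fibre_rejected(self, slab, conds):
        grid, fibers = slab
        broken = FiberField(vectors=np.zeros_like(fibers.vectors),
                            depth=fibers.depth, tissue_mask=fibers.tissue_mask)
        with pytest.raises(ValueError, match="fibre"):
            assemble_tensors(grid, broken, conds)

    def test_invalid_conductivities_rejected(self):
        with pytest.raises(ValueError):
            ConductivitySet(sigma_b=-1.0)
        with pytest.raises(ValueError):
            ConductivitySet(scale=0.0)


# ----------------------------------------------------------------- elliptic
def bath_box(n: int = 40):
    """1 cm x 1 cm pure bath with plate node sets on the x extremes."""
    lab = np.full((n, n), int(Label.BATH), dtype=np.int8)
    g = LabeledGrid(spacing_um=1.0e4 / n, cell_labels=lab)
    xi = np.indices(g.node_shape)[0]
    left = np.flatnonzero((xi == 0).ravel())
    right = np.flatnonzero((xi == n).ravel())
    return g, left, right


def empty_fibers(g):
    return FiberField(vectors=np.zeros(g.dims + (g.ndim,)),
                      depth=np.full(g.dims, np.nan),
                      tissue_mask=np.zeros(g.dims, bool))


class TestElliptic:
    def test_null_source_grounded_bath_is_zero(self):
        g, left, right = bath_box()
        ops = TissueOperators(g, empty_fibers(g), ConductivitySet())
        st = SimState(vm=np.zeros(0), phie=np.zeros(ops.n_a), membrane={})
        phie = ops.solve_elliptic(st, StimulusSet(
            dirichlet=[DirichletBC(right, 0.0)]))
        assert np.abs(phie).max() < 1e-9

    def test_plate_electrodes_linear_profile(self):
        g, left, right = bath_box()
        ops = TissueOperators(g, empty_fibers(g), ConductivitySet())
        st = SimState(vm=np.zeros(0), phie=np.zeros(ops.n_a), membrane={})
        phie = ops.solve_elliptic(st, StimulusSet(dirichlet=[
            DirichletBC(left, 1000.0), DirichletBC(right, 0.0)]))
        x = (np.indices(g.node_shape)[0] * g.spacing_cm).ravel()
        exact = 1000.0 * (1.0 - x[ops.active_nodes])
        assert np.abs(phie - exact).max() / 1000.0 < 1e-6

    def test_discrete_current_conservation(self):
        g, left, right = bath_box()
        ops = TissueOperators(g, empty_fibers(g), ConductivitySet())
        st = SimState(vm=np.zeros(0), phie=np.zeros(ops.n_a), membrane={})
        st.phie = ops.solve_elliptic(st, StimulusSet(dirichlet=[
            DirichletBC(left, 1000.0), DirichletBC(right, 0.0)]))
        i_in = ops.boundary_current(st, left)
        i_out = ops.boundary_current(st, right)
        assert abs(i_in + i_out) < 1e-8 * abs(i_in)

    def test_gauge_shift_leaves_vm_unchanged(self, slab_ops, model,
                                             slab_checkpoints):
        """Adding a constant to all Dirichlet values shifts phi_e only."""
        grid = slab_ops.grid
        elec = grid.node_sets["electrode_nodes"]
        gnd = grid.node_sets["ground_boundary"]
        base = slab_checkpoints[340.0]
        out = []
        for shift in (0.0, 137.0):
            st = base.copy()
            stim = StimulusSet(dirichlet=[
                DirichletBC(elec, 500.0 + shift), DirichletBC(gnd, shift)])
            slab_ops.step_bidomain(model, st, 0.005, 0.005, stim)
            out.append(st)
        dphi = out[1].phie - out[0].phie
        assert np.abs(dphi - 137.0).max() < 1e-8
        assert np.abs(out[1].vm - out[0].vm).max() < 1e-8


# ----------------------------------------------------------------- cable
class TestCablePhysics:
    def test_passive_steady_state_matches_cable_length_constant(self):
        conds = ConductivitySet()
        grid = build_strand(160, spacing_um=250.0)
        fib = assign_fibers_rule_based(grid)
        ops = TissueOperators(grid, fib, conds)
        gm = 0.1
        model = PassiveMembrane(g_m=gm)
        state = ops.initial_state(model)
        ns = grid.node_shape
        stim_nodes = np.array([0, 1])  # the x=0 node column
        st = StimulusSet(transmembrane=[
            Stimulus(strength=2000.0, t0=0.0, t1=1e9, nodes=stim_nodes)])
        for _ in range(400):
            ops.step_monodomain(model, state, 1.0, 1.0, st)
        lam = np.sqrt(conds.sm_ms_cm()[0] / (ops.beta * gm))
        x = (np.indices(ns)[0] * grid.spacing_cm).ravel()[grid.tissue_nodes()]
        dv = state.vm - model.v_rest
        sel = (x > 2 * lam) & (x < 6 * lam)
        slope = np.polyfit(x[sel], np.log(dv[sel]), 1)[0]
        assert abs(-1.0 / slope - lam) / lam < 0.02

    def test_equilibrium_preserved_without_stimuli(self, model, eq_state):
        grid = tissue_sheet(10)
        fib = assign_fibers_rule_based(grid)
        ops = TissueOperators(grid, fib, ConductivitySet())
        vm0, st0 = eq_state
        state = SimState(vm=np.full(ops.n_t, vm0), phie=np.zeros(ops.n_a),
                         membrane={k: np.full(ops.n_t, float(v[0]))
                                   for k, v in st0.items()})
        ops.run(model, state, 50.0, 0.02, mode="monodomain")
        assert np.abs(state.vm - vm0).max() < 0.01

    def test_zero_conductivity_limit_reproduces_single_cell(self, model,
                                                            eq_state):
        """s -> 0 decouples the nodes: every node follows the cell trace."""
        from veshock.membrane import run_single_cell

        vm0, st0 = eq_state
        grid = tissue_sheet(8)
        fib = assign_fibers_rule_based(grid)
        ops = TissueOperators(grid, fib, ConductivitySet(scale=1e-6))
        state = SimState(vm=np.full(ops.n_t, vm0), phie=np.zeros(ops.n_a),
                         membrane={k: np.full(ops.n_t, float(v[0]))
                                   for k, v in st0.items()})
        stim = StimulusSet(transmembrane=[
            Stimulus(strength=42000.0, t0=0.0, t1=2.0)])
        ops.run(model, state, 20.0, 0.02, stimuli=stim, mode="monodomain")
        tr = run_single_cell(model, 20.0, stim_times=[0.0], stim_amp=30.0,
                             vm0=vm0, state0=st0)
        assert np.abs(state.vm - tr.extras["vm_end"]).max() < 0.1

    def test_stability_abort_raises(self):
        grid = tissue_sheet(6)
        fib = assign_fibers_rule_based(grid)
        ops = TissueOperators(grid, fib, ConductivitySet(), vm_abort=100.0)
        model = PassiveMembrane()
        state = ops.initial_state(model)
        stim = StimulusSet(transmembrane=[
            Stimulus(strength=1e9, t0=0.0, t1=10.0)])
        with pytest.raises(StabilityError):
            ops.run(model, state, 5.0, 0.02, stimuli=stim)

    def test_dt_ordering_enforced(self, model):
        grid = tissue_sheet(6)
        fib = assign_fibers_rule_based(grid)
        ops = TissueOperators(grid, fib, ConductivitySet())
        state = ops.initial_state(model)
        with pytest.raises(ValueError):
            ops.step_monodomain(model, state, 0.1, 0.02, StimulusSet())


# ----------------------------------------------------------------- CV
class TestCVCalibration:
    def test_identity_target_short_circuits(self):
        assert calibrate_cv_scale(1.0) == 1.0

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cv_scale(0.0)
        with pytest.raises(ValueError):
            calibrate_cv_scale(-0.5)

    def test_planar_cv_finite_positive(self, conds):
        cv = measure_cv(conds, make_model)
        assert 20.0 < cv < 90.0
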