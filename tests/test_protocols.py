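"""Protocols: pacing equivalence, shock bookkeeping, null-shock controls."""
import numpy as np
import pytest

from conftest import tissue_sheet
from veshock.fibers import assign_fibers_rule_based
from veshock.protocols import (PacingSpec, ShockSpec, apply_shock,
                               precondition_and_checkpoint)
from veshock.solver import ConductivitySet, TissueOperators


class TestPacingSpec:
    def test_ci_beyond_bcl_rejected(self):
        with pytest.raises(ValueError, match="cycle length"):
            PacingSpec(bcl=500.0, cis=(600.0,))


@pytest.fixture(scope="module")
def small_ops(conds):
    grid = tissue_sheet(10)
    fib = assign_fibers_rule_based(grid)
    return TissueOperators(grid, fib, conds)


class TestUniformPacing:
    def test_tissue_path_stays_spatially_uniform(self, small_ops, model):
        """Uniform stimulus on uniform tissue: no propagation by symmetry."""
        pacing = PacingSpec(n_beats=1, bcl=300.0, cis=(120.0, 250.0))
        cps = precondition_and_checkpoint(small_ops, model, pacing,
                                          uniform_fast_path=False,
                                          equilibrate_ms=100.0)
        for st in cps.values():
            assert st.vm.max() - st.vm.min() < 0.1

    def test_tissue_path_matches_single_cell(self, small_ops, model,
                                             eq_state):
        """Uniform-field tissue equals the single-cell oracle within 0.5 mV."""
        from veshock.membrane import run_single_cell

        vm0, st0 = eq_state
        pacing = PacingSpec(n_beats=2, bcl=320.0, cis=(100.0, 300.0))
        cps = precondition_and_checkpoint(small_ops, model, pacing,
                                          uniform_fast_path=False,
                                          equilibrate_ms=50.0)
        # oracle: same protocol on one cell, starting cold like the tissue
        tr = run_single_cell(model, 50.0 + 320.0 + 300.0 + 0.1,
                             stim_times=[50.0, 370.0], stim_amp=30.0,
                             snapshot_times=[370.0 + ci for ci in
                                             (100.0, 300.0)])
        for ci in (100.0, 300.0):
            cell_vm = tr.extras["snapshots"][370.0 + ci][0]
            assert np.abs(cps[ci].vm - cell_vm).max() < 0.5

    def test_fast_path_agrees_with_tissue_path(self, small_ops, model):
        pacing = PacingSpec(n_beats=1, bcl=300.0, cis=(150.0,))
        fast = precondition_and_checkpoint(small_ops, model, pacing,
                                           equilibrate_ms=100.0)
        slow = precondition_and_checkpoint(small_ops, model, pacing,
                                           uniform_fast_path=False,
                                           equilibrate_ms=100.0)
        assert np.abs(fast[150.0].vm - slow[150.0].vm).max() < 0.5


class TestShockSpec:
    def test_polarity_signs(self, slab):
        grid, _ = slab
        a = ShockSpec.for_grid(grid, 5.0, "anodal")
        c = ShockSpec.for_grid(grid, 5.0, "cathodal")
        assert a.electrode_mv == 5000.0
        assert c.electrode_mv == -5000.0

    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            ShockSpec(voltage=-1.0)

    def test_electrode_ground_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ShockSpec(voltage=1.0, electrode=np.array([1, 2]),
                      ground=np.array([2, 3]))


class TestNullShock:
    def test_zero_voltage_matches_control(self, slab_ops, model,
                                          slab_checkpoints):
        """A 0 V shock is a floating electrode: identical continuation."""
        grid = slab_ops.grid
        shock = ShockSpec.for_grid(grid, 0.0, "anodal")
        run = apply_shock(slab_ops, model, slab_checkpoints[320.0], shock,
                          post_window=2.0, sample_times=(9.0, 12.0))
        for t in run.samples:
            assert np.abs(run.dvm(t)).max() < 0.01


def test_refractory_plateau_blocks_local_stimulus(conds, model, cell_paced):
    """A local suprathreshold stimulus propagates at a recovered CI but
    not during the late-plateau refractory state."""
    from conftest import broadcast_checkpoint
    from veshock.grid import build_strand
    from veshock.solver import Stimulus, StimulusSet, TissueOperators

    grid = build_strand(80, spacing_um=250.0)
    ops = TissueOperators(grid, assign_fibers_rule_based(grid), conds)
    _, cps = cell_paced
    ns = grid.node_shape
    stim_nodes = np.flatnonzero((np.indices(ns)[0] < 4).ravel())
    probe = int(ops.glob2tis[np.ravel_multi_index((60, 0), ns)])

    reached = {}
    for ci in (240.0, 340.0):
        state = broadcast_checkpoint(ops, cps, ci)
        baseline = state.vm[probe]
        stim = StimulusSet(transmembrane=[
            Stimulus(strength=70000.0, t0=0.0, t1=2.0, nodes=stim_nodes)])
        import copy
        m = copy.deepcopy(model)
        got = False
        for _ in range(int(80.0 / 0.02)):
            ops.step_monodomain(m, state, 0.02, 0.02, stim)
            if state.vm[probe] > baseline + 30.0:
                got = True
                break
        reached[ci] = got
    assert not reached[240.0]   # refractory: no propagated activation
    assert reached[340.0]       # recovered: wave reaches the probe
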