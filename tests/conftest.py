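"""Shared fixtures.

The expensive artefacts (single-cell equilibration, the paced-checkpoint
train, the standard slab operators) are session-scoped and shared across
test modules; everything is deterministic so sharing does not couple
tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from veshock import (ConductivitySet, PacingSpec, SlabConfig,
                     TissueOperators, assign_fibers_rule_based,
                     build_slab_with_trabecula)
from veshock.membrane import equilibrate, make_model
from veshock.protocols import precondition_and_checkpoint

#: coupling intervals used throughout: 220/240 refractory tail,
#: 280 late phase 3, 320/340 recovered
CIS = (220.0, 240.0, 280.0, 320.0, 340.0)


@pytest.fixture(scope="session")
def model():
    return make_model()


@pytest.fixture(scope="session")
def eq_state(model):
    """Quiescently equilibrated (vm, state) of the default membrane."""
    return equilibrate(model, duration=2000.0)


@pytest.fixture(scope="session")
def conds():
    """CV-reduced conductivities (25% slowing: scale = 0.5625)."""
    return ConductivitySet(scale=0.5625)


@pytest.fixture(scope="session")
def slab():
    """Standard detached-trabecula slab with its fibre field."""
    grid = build_slab_with_trabecula(SlabConfig())
    fibers = assign_fibers_rule_based(grid)
    return grid, fibers


@pytest.fixture(scope="session")
def slab_ops(slab, conds):
    grid, fibers = slab
    return TissueOperators(grid, fibers, conds)


@pytest.fixture(scope="session")
def cell_paced(model, eq_state):
    """Single-cell 5x500 ms pacing train with snapshots at the usual CIs.

    Shared source of truth: a uniformly stimulated uniform tissue equals
    the single cell exactly, so tissue checkpoints on any geometry are
    broadcasts of these states.
    """
    from veshock.membrane import paced_checkpoints

    return paced_checkpoints(model, cis=list(CIS), eq_state=eq_state)


def broadcast_checkpoint(ops, cell_cps, ci):
    """Tissue SimState from a single-cell checkpoint (uniform state)."""
    from veshock.solver import SimState

    vm, st = cell_cps[ci]
    return SimState(
        vm=np.full(ops.n_t, vm), phie=np.zeros(ops.n_a),
        membrane={k: np.full(ops.n_t, float(np.asarray(v).ravel()[0]))
                  for k, v in st.items()}, t=0.0)


@pytest.fixture(scope="session")
def slab_checkpoints(slab_ops, cell_paced):
    """Uniform-pacing checkpoints on the standard slab at the usual CIs."""
    _, cps = cell_paced
    return {ci: broadcast_checkpoint(slab_ops, cps, ci) for ci in CIS}


@pytest.fixture(scope="session")
def attached_slab(conds):
    grid = build_slab_with_trabecula(SlabConfig(trabecula="attached"))
    fibers = assign_fibers_rule_based(grid)
    return grid, TissueOperators(grid, fibers, conds)


def tissue_sheet(n: int = 24, spacing_um: float = 250.0):
    """Plain all-tissue 2-D sheet with endo/epi faces on the y extremes."""
    from veshock.grid import LabeledGrid, Label

    lab = np.full((n, n), int(Label.TISSUE), dtype=np.int8)
    grid = LabeledGrid(spacing_um=spacing_um, cell_labels=lab)
    ns = grid.node_shape
    jj = np.indices(ns)[1]
    grid.node_sets = {
        "endocardium": np.flatnonzero((jj == n).ravel()),
        "epicardium": np.flatnonzero((jj == 0).ravel()),
    }
    return grid
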