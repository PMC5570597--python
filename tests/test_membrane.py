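"""Membrane models: resting stability, AP morphology, restitution,
augmentation currents, integration accuracy."""
import copy

import numpy as np
import pytest

from veshock.membrane import (MembraneParams, TP06Model, TT04Model, apd90,
                              make_model, run_single_cell, validate_state)
from veshock.membrane.augment import (AugmentationParams,
                                      augmentation_currents, k_aug_current)


@pytest.fixture()
def paced(cell_paced):
    """5 beats at BCL 500 with checkpoints at the standard CIs."""
    return cell_paced


class TestRestingState:
    def test_quiescent_equilibrium(self, model, eq_state):
        vm, st = eq_state
        assert -88.0 < vm < -84.0
        i = model.ionic_current(np.array([vm]), st)
        assert abs(float(i[0])) < 0.01
        # state derivatives: one more step changes nothing appreciably
        st2 = {k: v.copy() for k, v in st.items()}
        vm2 = np.array([vm])
        for _ in range(int(10 / 0.02)):  # zero-current continuation, 10 ms
            i = model.step(vm2, st2, 0.02)
            vm2 = vm2 + 0.02 * (-i)
        assert abs(float(vm2[0]) - vm) < 1e-2
        for k in st:
            assert np.allclose(st2[k], st[k], atol=1e-4)

    def test_nonfinite_vm_rejected(self, model, eq_state):
        _, st = eq_state
        with pytest.raises(ValueError):
            model.ionic_current(np.array([np.nan]), st)

    def test_gate_clamped_outside_unit_interval_rejected(self, model,
                                                         eq_state):
        _, st = eq_state
        bad = {k: v.copy() for k, v in st.items()}
        bad["h"] = np.array([1.7])
        with pytest.raises(ValueError, match="gating"):
            validate_state(bad)


class TestActionPotential:
    def test_suprathreshold_beat_morphology(self, model, eq_state):
        vm0, st0 = eq_state
        tr = run_single_cell(model, 500.0, stim_times=[0.0], stim_amp=30.0,
                            vm0=vm0, state0=st0)
        assert tr.vm.max() > 20.0
        assert tr.vm[-1] < -80.0  # repolarised within 500 ms

    def test_apd90_restitution_band(self, paced):
        """APD90 of the 5th beat at cycle length 500 lies in 250-350 ms."""
        tr, _ = paced
        sel = tr.t >= 2000.0
        a = apd90(tr.t[sel], tr.vm[sel])
        assert 250.0 <= a <= 350.0

    def test_refractoriness_landscape(self, paced):
        """Late-phase-3 at short CIs, full recovery by 320-340 ms."""
        _, cps = paced
        assert cps[240.0][0] > -45.0     # relatively refractory
        assert cps[340.0][0] < -80.0     # recovered
        assert cps[220.0][0] > cps[280.0][0] > cps[340.0][0]

    def test_time_step_convergence(self, model, eq_state):
        """Halving dt from 0.02 to 0.005 moves APD90 by < 1 ms."""
        vm0, st0 = eq_state
        apds = []
        for dt in (0.02, 0.01, 0.005):
            tr = run_single_cell(model, 400.0, dt=dt, stim_times=[0.0],
                                 stim_amp=30.0, vm0=vm0, state0=st0)
            apds.append(apd90(tr.t, tr.vm))
        assert abs(apds[0] - apds[2]) < 1.0
        assert abs(apds[1] - apds[2]) < abs(apds[0] - apds[2]) + 0.1

    def test_determinism(self, model, eq_state):
        vm0, st0 = eq_state
        tr1 = run_single_cell(model, 50.0, stim_times=[0.0], stim_amp=30.0,
                              vm0=vm0, state0=st0)
        tr2 = run_single_cell(model, 50.0, stim_times=[0.0], stim_amp=30.0,
                              vm0=vm0, state0=st0)
        assert np.array_equal(tr1.vm, tr2.vm)


class TestAugmentation:
    def test_virgin_membrane_no_augmentation_current(self):
        i = augmentation_currents(np.array([-85.0]), np.array([0.0]))
        assert abs(float(i[0])) < 1e-9

    def test_k_current_threshold_selectivity(self):
        """Negligible at +100 mV relative to +200 mV (recruited > +160)."""
        i100 = float(k_aug_current(np.array([100.0]))[0])
        i200 = float(k_aug_current(np.array([200.0]))[0])
        assert i100 < 0.01 * i200

    def test_sustained_positive_clamp_more_outward_with_augmentation(self,
                                                                     eq_state):
        vm0, st0 = eq_state
        on = make_model()
        off = make_model(params=MembraneParams(electroporation=False,
                                               k_current=False))
        st_on = {k: v.copy() for k, v in st0.items()}
        st_off = {k: v.copy() for k, v in st0.items()}
        clamp = np.array([200.0])
        for _ in range(int(10 / 0.005)):
            i_on = on.step(clamp.copy(), st_on, 0.005)
            i_off = off.step(clamp.copy(), st_off, 0.005)
            assert float(i_on[0]) > float(i_off[0])

    def test_disabled_augmentation_identically_zero(self):
        p = MembraneParams(electroporation=False, k_current=False)
        i = augmentation_currents(np.array([250.0]), np.array([5.0]),
                                  electroporation=False, k_current=False)
        assert float(i[0]) == 0.0

    def test_augmentation_inert_at_physiological_potentials(self, eq_state):
        """From a virgin pore state, one paced beat with/without the
        augmentation currents differs by < 0.1 mV."""
        vm0, st0 = eq_state
        virgin = {k: v.copy() for k, v in st0.items()}
        virgin["n_pore"] = np.zeros_like(virgin["n_pore"])
        on = make_model()
        off = make_model(params=MembraneParams(electroporation=False,
                                               k_current=False))
        kw = dict(stim_times=[0.0], stim_amp=30.0, vm0=vm0, record_dt=1.0)
        tr_on = run_single_cell(on, 450.0, state0=virgin, **kw)
        tr_off = run_single_cell(off, 450.0, state0=virgin, **kw)
        assert np.abs(tr_on.vm - tr_off.vm).max() < 0.1


class TestVariants:
    @pytest.mark.parametrize("cls", [TP06Model, TT04Model])
    def test_both_generations_rest_near_minus_86(self, cls):
        m = cls()
        vm = m.initial_vm(1)
        st = m.initial_state(1)
        for _ in range(int(200 / 0.02)):
            i = m.step(vm, st, 0.02)
            vm = vm + 0.02 * (-i)
        assert -88.0 < float(vm[0]) < -84.0

    def test_unknown_model_name_rejected(self):
        with pytest.raises(ValueError, match="unknown membrane model"):
            make_model("not_a_model")

    def test_dt_must_be_positive(self, model, eq_state):
        vm0, st0 = eq_state
        with pytest.raises(ValueError):
            model.step(np.array([vm0]), copy.deepcopy(st0), -0.01)
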