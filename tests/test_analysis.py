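"""Analysis statistics: fractions, filaments, resistance, energy."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veshock.analysis import (compute_resistance, count_phase_singularities,
                              detect_filaments, field_strength_fraction,
                              shock_energy, shock_energy_waveform,
                              threshold_fraction)
from veshock.fibers import FiberField
from veshock.grid import Label, LabeledGrid
from veshock.solver import (ConductivitySet, DirichletBC, SimState,
                            StimulusSet, TissueOperators)
from veshock.spirals import SpiralField, figure_of_eight, random_spiral_suite


# ----------------------------------------------------------------- fractions
class TestThresholdFraction:
    def test_all_below(self):
        assert threshold_fraction(np.full(50, -86.0), np.arange(50),
                                  -20.0, "above") == 0.0

    def test_all_above(self):
        assert threshold_fraction(np.zeros(50), np.arange(50),
                                  -20.0, "above") == 100.0

    def test_exact_count(self):
        vm = np.full(100, -50.0)
        vm[:37] = 0.0
        assert threshold_fraction(vm, np.arange(100), -20.0, "above") == 37.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_fraction(np.zeros(5), np.array([], dtype=int), 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 50), min_size=1, max_size=60),
           st.floats(-90, 40), st.floats(0, 50))
    def test_monotone_in_threshold(self, vals, thr, bump):
        vm = np.array(vals)
        idx = np.arange(vm.size)
        hi = threshold_fraction(vm, idx, thr + bump, "above")
        lo = threshold_fraction(vm, idx, thr, "above")
        assert hi <= lo


# ----------------------------------------------------------------- filaments
def all_tissue_grid(node_shape, nz=0):
    dims = tuple(n - 1 for n in node_shape) + ((nz,) if nz else ())
    lab = np.full(dims, int(Label.TISSUE), dtype=np.int8)
    return LabeledGrid(spacing_um=250.0, cell_labels=lab)


class TestFilaments:
    SHAPE = (48, 48)

    def test_resting_frames_have_no_filaments(self):
        g = all_tissue_grid(self.SHAPE)
        rest = np.full(self.SHAPE, -85.0)
        assert detect_filaments(rest.ravel(), rest.ravel(), 1.0, g).count == 0

    def test_single_extruded_spiral_is_one_filament(self):
        sp = SpiralField(centers=[(24.0, 24.0)], chirality=[1])
        a, b = sp.extruded_frames(self.SHAPE, 10, t=5.0)
        g = all_tissue_grid(self.SHAPE, nz=9)
        assert detect_filaments(a.ravel(), b.ravel(), 1.0, g).count == 1
        assert count_phase_singularities(*sp.frames(self.SHAPE, 5.0)) == 1

    def test_figure_of_eight_is_two_filaments(self):
        f8 = figure_of_eight(self.SHAPE)
        a, b = f8.extruded_frames(self.SHAPE, 10, t=3.0)
        g = all_tissue_grid(self.SHAPE, nz=9)
        assert detect_filaments(a.ravel(), b.ravel(), 1.0, g).count == 2
        now, prev = f8.frames(self.SHAPE, 3.0)
        assert count_phase_singularities(now, prev) == 2
        # opposite chirality: total charge zero
        from veshock.analysis import phase_singularities_2d
        charges = [c for _, _, c in phase_singularities_2d(now, prev)]
        assert sum(charges) == 0

    def test_random_suite_matches_phase_winding_oracle(self):
        g = all_tissue_grid(self.SHAPE, nz=5)
        for case in random_spiral_suite(20, shape=self.SHAPE, seed=7):
            expected = len(case.centers)
            ps = count_phase_singularities(*case.frames(self.SHAPE, t=2.0))
            a, b = case.extruded_frames(self.SHAPE, 6, t=2.0)
            fc = detect_filaments(a.ravel(), b.ravel(), 1.0, g).count
            assert ps == expected
            assert fc == expected

    def test_mismatched_frames_rejected(self):
        g = all_tissue_grid(self.SHAPE)
        with pytest.raises(ValueError, match="mismatch"):
            detect_filaments(np.zeros(10), np.zeros(12), 1.0, g)


# ----------------------------------------------------------------- circuit
def bath_fixture(n, spacing_um):
    lab = np.full((n, n), int(Label.BATH), dtype=np.int8)
    g = LabeledGrid(spacing_um=spacing_um, cell_labels=lab)
    fib = FiberField(vectors=np.zeros((n, n, 2)),
                     depth=np.full((n, n), np.nan),
                     tissue_mask=np.zeros((n, n), bool))
    return g, fib


class TestResistance:
    def solve(self, sigma_b=1.0, n=40, v_mv=1000.0):
        g, fib = bath_fixture(n, 1.0e4 / n)
        ops = TissueOperators(g, fib, ConductivitySet(sigma_b=sigma_b))
        xi = np.indices(g.node_shape)[0]
        left = np.flatnonzero((xi == 0).ravel())
        right = np.flatnonzero((xi == n).ravel())
        st = SimState(vm=np.zeros(0), phie=np.zeros(ops.n_a), membrane={})
        st.phie = ops.solve_elliptic(st, StimulusSet(dirichlet=[
            DirichletBC(left, v_mv), DirichletBC(right, 0.0)]))
        return ops, st, left, right

    def test_slab_resistance_analytic(self):
        """1 cm bath cube at 1 S/m between plates: R = L/(sigma A) = 100 Ω."""
        ops, st, left, right = self.solve()
        r = compute_resistance(ops, st, 1000.0, left, right)
        assert r == pytest.approx(100.0, rel=0.01)

    def test_resistance_invariant_to_test_voltage(self):
        ops, st, left, right = self.solve(v_mv=1000.0)
        r1 = compute_resistance(ops, st, 1000.0, left, right)
        ops2, st2, l2, r2_ = self.solve(v_mv=3000.0)
        r2 = compute_resistance(ops2, st2, 3000.0, l2, r2_)
        assert abs(r1 - r2) / r1 < 0.01

    def test_doubling_sigma_halves_resistance(self):
        ops1, st1, l1, r1_ = self.solve(sigma_b=1.0)
        ops2, st2, l2, r2_ = self.solve(sigma_b=2.0)
        ra = compute_resistance(ops1, st1, 1000.0, l1, r1_)
        rb = compute_resistance(ops2, st2, 1000.0, l2, r2_)
        assert abs(ra - 2.0 * rb) < 1e-8 * ra

    def test_annulus_resistance_closed_form(self):
        """Concentric electrodes: R per unit depth = ln(b/a)/(2 pi sigma)."""
        n = 320
        g, fib = bath_fixture(n, 1.0e4 / n)
        ops = TissueOperators(g, fib, ConductivitySet())
        nodes = np.indices(g.node_shape).astype(float)
        c = n / 2.0
        r = np.hypot(nodes[0] - c, nodes[1] - c)
        a_cells, b_cells = 40.0, 150.0
        inner = np.flatnonzero((r <= a_cells).ravel())
        outer = np.flatnonzero((r >= b_cells).ravel())
        st = SimState(vm=np.zeros(0), phie=np.zeros(ops.n_a), membrane={})
        st.phie = ops.solve_elliptic(st, StimulusSet(dirichlet=[
            DirichletBC(inner, 1000.0), DirichletBC(outer, 0.0)]))
        r_num = compute_resistance(ops, st, 1000.0, inner, outer)
        sigma = 0.01  # 1 S/m in S/cm
        r_exact = np.log(b_cells / a_cells) / (2 * np.pi * sigma)
        assert abs(r_num - r_exact) / r_exact < 0.02

    def test_zero_current_rejected(self):
        ops, st, left, right = self.solve()
        st.phie = np.zeros_like(st.phie)
        with pytest.raises(ValueError, match="zero"):
            compute_resistance(ops, st, 0.0, left, right)


class TestShockEnergy:
    def test_printed_energy_values(self):
        # V^2 T / R with R = 36.4 Ω, T = 10 ms square pulses
        assert shock_energy(10.0, 10.0, 36.4) == pytest.approx(0.027, abs=5e-4)
        assert shock_energy(1.0, 10.0, 36.4) == pytest.approx(0.0003,
                                                              abs=5e-5)

    def test_null_shock(self):
        assert shock_energy(0.0, 10.0, 36.4) == 0.0

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            shock_energy(5.0, 10.0, 0.0)

    def test_waveform_integral_matches_square_pulse(self):
        t = np.linspace(0.0, 10.0, 2001)
        v = np.full_like(t, 5.0)
        assert shock_energy_waveform(t, v, 36.4) == pytest.approx(
            shock_energy(5.0, 10.0, 36.4), rel=1e-9)


class TestFieldStrength:
    def make_uniform(self, v_per_cm):
        n = 20
        lab = np.full((n, n), int(Label.TISSUE), dtype=np.int8)
        g = LabeledGrid(spacing_um=1.0e4 / n, cell_labels=lab)
        from veshock.fibers import assign_fibers_rule_based
        ns = g.node_shape
        jj = np.indices(ns)[1]
        g.node_sets = {"endocardium": np.flatnonzero((jj == n).ravel()),
                       "epicardium": np.flatnonzero((jj == 0).ravel())}
        fib = assign_fibers_rule_based(g)
        ops = TissueOperators(g, fib, ConductivitySet())
        x = (np.indices(ns)[0] * g.spacing_cm).ravel()[ops.active_nodes]
        phie = v_per_cm * 1000.0 * x  # mV
        return ops, phie

    def test_uniform_field_thresholds(self):
        ops, phie = self.make_uniform(1.0)
        assert field_strength_fraction(phie, ops, 0.5) == 100.0
        assert field_strength_fraction(phie, ops, 2.0) == 0.0

    def test_gradient_accuracy(self):
        ops, phie = self.make_uniform(1.0)
        # every cell within 1% of 1 V/cm: thresholds bracketing tightly
        assert field_strength_fraction(phie, ops, 0.99) == 100.0
        assert field_strength_fraction(phie, ops, 1.01) == 0.0
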