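"""Synthetic geometry: labels, node sets, detachment topology."""
import numpy as np
import pytest

from veshock.grid import (AnnulusConfig, Label, SlabConfig,
                          build_annulus_cavity, build_slab_with_trabecula,
                          detachment_holds)


class TestSlabBuilder:
    def test_label_counts_match_configured_products(self):
        # 60-wide slab, wall 10, trabecula 20x3 over a 20x2 cleft
        cfg = SlabConfig(nx=60, wall=10, trab_length=20, trab_thickness=3,
                         cleft=2, bath_below=2, electrode_offset=3,
                         bath_above=3, electrode_margin=8)
        g = build_slab_with_trabecula(cfg)
        labels, counts = np.unique(g.cell_labels, return_counts=True)
        by = dict(zip(labels.tolist(), counts.tolist()))
        assert by[int(Label.TISSUE_TRABECULA)] == 20 * 3
        assert by[int(Label.CLEFT_BATH)] == 20 * 2

    def test_detached_trabecula_topology(self):
        g = build_slab_with_trabecula(SlabConfig())
        assert detachment_holds(g)
        _, n = g.tissue_components()
        assert n == 1  # attachments keep the strand wall-connected

    def test_attached_ridge_is_not_detached(self):
        g = build_slab_with_trabecula(SlabConfig(trabecula="attached"))
        assert not detachment_holds(g)
        assert g.node_sets["trabecula_distal_face"].size == 0

    def test_plain_wall_is_simply_connected_with_planar_endocardium(self):
        g = build_slab_with_trabecula(SlabConfig(trabecula="none"))
        _, n = g.tissue_components()
        assert n == 1
        assert g.node_sets["trabecula_proximal_face"].size == 0
        assert g.node_sets["trabecula_distal_face"].size == 0
        # endocardium all at one height -> planar
        ys = np.unravel_index(g.node_sets["endocardium"], g.node_shape)[1]
        assert np.unique(ys).size == 1

    def test_zero_cleft_detached_rejected(self):
        with pytest.raises(ValueError, match="cleft"):
            build_slab_with_trabecula(SlabConfig(cleft=0))

    def test_oversized_trabecula_rejected(self):
        with pytest.raises(ValueError):
            build_slab_with_trabecula(SlabConfig(nx=20, trab_length=20))

    def test_node_sets_disjoint_and_on_interface(self):
        g = build_slab_with_trabecula(SlabConfig())
        iface = set(g.interface_nodes().tolist())
        names = ["endocardium", "epicardium", "trabecula_proximal_face",
                 "trabecula_distal_face"]
        seen: set[int] = set()
        for name in names:
            s = set(g.node_sets[name].tolist())
            assert not (s & seen), f"{name} overlaps another surface set"
            assert s <= iface, f"{name} node off the tissue/bath interface"
            seen |= s

    def test_electrode_inside_bath_ground_on_boundary(self):
        g = build_slab_with_trabecula(SlabConfig())
        elec = np.argwhere(g.cell_labels == Label.ELECTRODE)
        # neighbours of electrode cells are bath-conducting only
        for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = g.cell_labels[tuple((elec + d).T)]
            assert np.all(np.isin(nb, [int(Label.BATH), int(Label.ELECTRODE)]))
        gnd = np.argwhere(g.cell_labels == Label.GROUND)
        assert np.all(gnd[:, 1] == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_detachment_across_randomised_configs(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SlabConfig(
            nx=int(rng.integers(48, 90)),
            wall=int(rng.integers(6, 16)),
            trab_length=int(rng.integers(8, 18)),
            trab_thickness=int(rng.integers(1, 4)),
            cleft=int(rng.integers(1, 4)),
            n_trabeculae=int(rng.integers(1, 3)),
            seed=seed)
        g = build_slab_with_trabecula(cfg)
        assert detachment_holds(g)

    def test_3d_extrusion_keeps_topology(self):
        g = build_slab_with_trabecula(SlabConfig(nz=4))
        assert g.ndim == 3
        assert detachment_holds(g)


class TestAnnulusBuilder:
    def test_no_trabeculae_rotationally_symmetric(self):
        g = build_annulus_cavity(AnnulusConfig())
        assert np.array_equal(g.cell_labels, np.rot90(g.cell_labels))

    def test_four_trabeculae_detached_components(self):
        g = build_annulus_cavity(AnnulusConfig(n_trabeculae=4, seed=3))
        _, n = g.tissue_components(g.cell_labels == Label.TISSUE_TRABECULA)
        assert n == 4
        assert detachment_holds(g)

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            build_annulus_cavity(AnnulusConfig(r_endo=0.0))

    def test_thin_wall_rejected(self):
        with pytest.raises(ValueError, match="wall"):
            build_annulus_cavity(AnnulusConfig(wall=2.0))
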