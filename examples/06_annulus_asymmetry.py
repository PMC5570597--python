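"""Anodal/cathodal asymmetry in a trabeculated annular cavity.

A central line electrode in a blood-filled cavity produces a radial
field: strong on the endocardium, weak on the epicardium.  10 V shocks
of both polarities are applied to recovered tissue and the fraction of
the whole wall activated 10 ms post-shock is compared.

Expected outcome: the anodal shock activates far more tissue.  It
captures the (outer, larger) epicardial surface and seeds make
excitations at the wall-facing sides of the detached trabeculae, while
the shock-hyperpolarised endocardium is left immediately re-excitable;
the cathodal shock captures only the endocardial surface.  With a
passive (linear) membrane the two polarities are exact mirror images --
the asymmetry is created by the active dynamics.
"""
import numpy as np

from veshock import (AnnulusConfig, ConductivitySet, PacingSpec, ShockSpec,
                     TissueOperators, apply_shock, assign_fibers_rule_based,
                     build_annulus_cavity, precondition_and_checkpoint,
                     threshold_fraction, ve_polarity_summary)
from veshock.membrane import PassiveMembrane, make_model

grid = build_annulus_cavity(AnnulusConfig(n=72, r_endo=16.0, wall=10.0,
                                          n_trabeculae=4, seed=0,
                                          trab_thickness=2.0, cleft=2.0,
                                          trab_arc_deg=30.0))
conds = ConductivitySet(scale=0.5625)
ops = TissueOperators(grid, assign_fibers_rule_based(grid), conds)

# passive control: exact antisymmetry
passive = PassiveMembrane()
state = ops.initial_state(passive)
runs = {}
for pol in ("anodal", "cathodal"):
    runs[pol] = apply_shock(ops, passive, state,
                            ShockSpec.for_grid(grid, 5.0, pol),
                            post_window=0.5, sample_times=(5.0,))
mirror = np.abs(runs["anodal"].dvm(5.0) + runs["cathodal"].dvm(5.0)).max()
print(f"passive membrane: max |ΔVm(anodal) + ΔVm(cathodal)| = {mirror:.2e} mV")

# active comparison at a recovered coupling interval
model = make_model()
cps = precondition_and_checkpoint(ops, model, PacingSpec(cis=(340.0,)))
print("\nactive tissue, 10 V shocks at CI 340 ms:")
for pol in ("anodal", "cathodal"):
    rec = apply_shock(ops, model, cps[340.0],
                      ShockSpec.for_grid(grid, 10.0, pol), post_window=10.0)
    frac = threshold_fraction(rec.samples[20.0], np.arange(ops.n_t),
                              -20.0, "above")
    print(f"  {pol:8s}: {frac:5.1f}% of the wall activated 10 ms post-shock")
print("\nThe passive mirror symmetry shows the asymmetry is not in the"
      "\nfield equations; it emerges from membrane dynamics + geometry.")
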