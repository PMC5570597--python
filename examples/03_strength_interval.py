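"""Endocardial capture vs shock strength and coupling interval.

Anodal shocks of 1-10 V are applied to the detached-trabecula slab at a
refractory (240 ms) and a recovered (340 ms) coupling interval; the
percentage of the endocardial surface activated (Vm > -20 mV) is printed
at shock-end (9 ms) and 10 ms post-shock (20 ms).

Expected trends: at the recovered CI the post-shock activated fraction
grows (weakly monotonically) with shock strength as make excitations
propagate; at the refractory CI only the strong shock achieves lasting
capture (break excitations into shock-hyperpolarised tissue), while the
weakest shock's activation dies away after shock-end.
"""
import numpy as np

from veshock import (ConductivitySet, PacingSpec, ShockSpec, SlabConfig,
                     TissueOperators, apply_shock,
                     assign_fibers_rule_based, build_slab_with_trabecula,
                     precondition_and_checkpoint, threshold_fraction)
from veshock.membrane import make_model

model = make_model()
grid = build_slab_with_trabecula(SlabConfig())
ops = TissueOperators(grid, assign_fibers_rule_based(grid),
                      ConductivitySet(scale=0.5625))
cps = precondition_and_checkpoint(ops, model, PacingSpec(cis=(240.0, 340.0)))

endo = ops.glob2tis[grid.node_sets["endocardium"]]
endo = endo[endo >= 0]

all_tissue = np.arange(ops.n_t)
print(f"{'CI (ms)':>8} {'V':>5} {'endo% @9ms':>11} {'endo% @20ms':>12} "
      f"{'tissue% @20ms':>14}")
for ci in (340.0, 240.0):
    for v in (1.0, 3.0, 5.0, 10.0):
        rec = apply_shock(ops, model, cps[ci],
                          ShockSpec.for_grid(grid, v, "anodal"),
                          post_window=10.0)
        f9 = threshold_fraction(rec.samples[9.0], endo, -20.0, "above")
        f20 = threshold_fraction(rec.samples[20.0], endo, -20.0, "above")
        t20 = threshold_fraction(rec.samples[20.0], all_tissue, -20.0,
                                 "above")
        print(f"{ci:8.0f} {v:5.0f} {f9:11.1f} {f20:12.1f} {t20:14.1f}")
print("\nAt CI 340 the +10 ms endocardial capture rises with voltage (make"
      "\nexcitations). At CI 240 the endocardium stays hyperpolarised;"
      "\nstronger shocks hold captured tissue at +10 ms (break excitations"
      "\nfrom the depolarised trabecular/epicardial surfaces, more with"
      "\nhigher voltage) while the weakest shock's activation dies away.")
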