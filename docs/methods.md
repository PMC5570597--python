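# Methods

`veshock` studies how monophasic shocks from an intracavitary electrode
interact with fine endocardial structure — specifically *detached
trabeculae*, muscular strands joined to the wall only at their ends with
a blood-filled cleft beneath the mid-span — to form virtual electrodes
(VEs) and polarity-asymmetric excitation. Everything runs at desk scale
on synthetic geometries; nothing here claims to reproduce whole-heart
absolute numbers, only the mechanisms and their signs/trends.

## Tissue model

Electrical activity follows the bidomain equations: intracellular and
extracellular potentials φi, φe on tissue, a passive conductive bath,
Vm = φi − φe, with membrane dynamics

    β Cm ∂Vm/∂t = ∇·σi∇(Vm + φe) − β I_ion(Vm, η) + I_s
    ∇·(σi+σe)∇φe = −∇·σi∇Vm          (tissue)
    ∇·σb∇φe = −I_eb                   (bath)

No-flux conditions hold for φi at tissue boundaries and for φe on outer
non-ground boundaries; φe is continuous across the tissue–bath interface
and clamped (Dirichlet) on electrode and ground node sets. When σe ∝ σi
the system reduces to the monodomain equation with the harmonic-mean
tensor σm = σiσe/(σi+σe) per eigendirection; the monodomain form is used
for pacing and arrhythmia evolution, the bidomain form whenever a shock
is applied — mirroring standard practice for this protocol family.

**Parameters.** σi = (0.174, 0.0193) S/m, σe = (0.625, 0.236) S/m
(longitudinal, transverse), σb = 1.0 S/m; β = 1400 cm⁻¹ and
Cm = 1 µF/cm² (standard bidomain values); internal units mV/ms/cm/mS/cm
(1 S/m = 10 mS/cm), under which every term of the parabolic balance is
µA/cm³ with no hidden prefactors. A uniform scale `s` multiplies σi and
σe only; `calibrate_cv_scale(0.75)` bisects `s` until a planar strand's
conduction velocity is 75% of baseline, emulating gap-junction
remodelling (cable theory predicts s ≈ 0.75² = 0.5625, and the
calibrated value is within a few percent of that). Calibration measures
CV on a 125 µm strand, one refinement below the 250 µm tissue default,
because at 250 µm lattice discreteness biases low-σ velocities upward.

## Discretisation

Lumped-mass Q1 finite elements (bilinear/trilinear) on uniform
axis-aligned grids; cell-centred labels and conductivity tensors,
node-centred potentials. Q1 elements were chosen over two-point-flux
finite volumes because rotated fibre tensors have off-diagonal entries
that two-point fluxes cannot represent; the assembled stiffness matrices
still have exactly zero row sums, so the discrete current entering
through the electrode equals the current leaving through ground to
solver precision — the identity behind the resistance integral
R = V / ∮ σb∇φe·n̂ dS. Time integration is first-order operator
splitting: Rush–Larsen membrane updates (gates via exponential
integration, hence always in [0,1]) and an explicit Vm reaction step,
then an implicit parabolic diffusion solve and, for the bidomain, a
sparse-LU extracellular solve with Dirichlet elimination;
factorisations are cached per (matrix, dt) and per electrode
configuration. Default steps follow the protocol family: 0.02 ms for
pacing/arrhythmia, 0.005 ms during shocks. The splitting error in the
bidomain↔monodomain equal-anisotropy identity is first-order in the PDE
step (≈0.2 mV at 0.005 ms on a paced-beat test).

The fibre rule assigns transmural depth d by a Laplace solve with
Dirichlet 0/1 on endo-/epicardial node sets — done on an edge-based
graph Laplacian (an M-matrix), so d obeys the discrete maximum
principle, which trilinear FEM would not guarantee — then inclines the
circumferential vector from +60° (endo) to −60° (epi) linearly in d
(the linear form is our choice; only "based on the normalised
transmural distance" is prescribed by the protocol family). Trabecular
cells get fibres along the structure axis (the slab's x axis, or the
local azimuth in the annulus).

A stability guard aborts any step driving |Vm| beyond 1500 mV. Strong
shocks legitimately polarise surface tissue by several hundred mV
before the augmentation currents clamp, so the guard is deliberately
far outside that range.

## Membrane models

Two published human ventricular generations are implemented
(epicardial parameter sets, uniform — no transmural heterogeneity):

* **2004 generation** (default): single cytosolic Ca pool, Ca-gated
  L-type inactivation, voltage/Ca release gate. Validation: resting
  −86.3 mV; first-beat APD90 278 ms against the published 276 ms.
* **2006 generation**: dyadic-subspace Ca cycling. Validation: resting
  −86.0 mV, APD90 301.5 ms against the published ~301 ms.

The 2004 model is the default because its late-phase-3 course at a
500 ms cycle length matches the refractoriness landscape the shock
protocols are defined on: after 5 conditioning beats it reads −23.9 mV
at a 240 ms coupling interval ("relatively refractory") and is fully
recovered by 320–340 ms. Neither generation reaches −25 mV as early as
CI 220 (2004: −10.1 mV; 2006: −1.3 mV); that would require APD90 ≈
255 ms, below both models at this rate. The acceptance harness reports
the computed value as-is.

**Shock augmentation.** Two currents reproduce the asymmetric membrane
response to strong shocks; the canonical studies cite them without
printing constants, so the constants here are literature-representative
and collected in one dataclass (`AugmentationParams`):

* *Electroporation*: normalised pore density
  dn/dt = a·e^{(Vm/Vep)²}(1 − n·e^{−q(Vm/Vep)²}) with Vep = 258 mV,
  q = 2.46, a = 5·10⁻⁷ ms⁻¹, and ohmic pore current I_ep = g_ep·n·Vm with
  g_ep = 0.2 mS/cm². With these magnitudes pore formation is
  electrically negligible at physiological potentials over seconds and
  clamps excursions near ±0.9 V within milliseconds.
* *High-voltage K⁺ current*: instantaneously gated outward current with
  a sigmoidal activation centred 20 mV above the +160 mV threshold
  (slope 8 mV), negligible below the threshold (at +100 mV it is <1% of
  its +200 mV value).

Both are toggleable; disabled they contribute exactly zero, and enabled
they change a physiological paced beat by <0.1 mV.

Uniform pacing uses a transmembrane stimulus of 2 ms at 42 mA/cm³
(30 µA/cm² per membrane area with β = 1400 cm⁻¹), a standard
suprathreshold amplitude; the per-membrane form is what enters the
equations, so only the ratio strength/β matters.

A two-variable cubic excitable model and a linear-leak passive membrane
exist for solver tests only (cable length-constant and antisymmetry
closed forms); they never produce headline physiology.

## Synthetic geometries — what they emulate and what they do not

* **Slab** (`build_slab_with_trabecula`): an endocardial wall (default
  40 cells × 250 µm = 1 cm) under a bath with a plate-like electrode,
  grounded below the epicardium; a detached trabecula (20×3 cells) runs
  parallel to the wall over a 2-cell cleft, attached by single-column
  end struts; the attached-ridge and plain-wall variants are controls.
  This reproduces the *local* VE mechanism — transmural current
  entering the proximal trabecular surface (hyperpolarising), leaving
  the distal surface (depolarising), re-entering the endocardium — and
  the strength/coupling-interval trends of endocardial capture.
* **Annulus** (`build_annulus_cavity`): an annular wall around a
  blood-filled cavity with a central electrode and grounded rim; the
  field decays radially, so the endocardium sits in a strong field and
  the epicardium in a weak one, as in a real cavity. Detached
  trabeculae are azimuthal arcs bridged to the wall by radial spokes.
  The anodal/cathodal *activated-volume* asymmetry is evaluated here:
  a plate-ground slab is mirror-symmetric between its two surfaces
  under polarity reversal, so that asymmetry cancels by construction —
  measuring it on the slab would test the geometry artefact, not the
  mechanism. On the annulus, a 10 V anodal shock at a recovered
  coupling interval activates the whole wall within 10 ms post-shock
  while the cathodal shock reaches roughly 60%.

Neither geometry has apex–base curvature, transmural cell-type
gradients, coronary vessels, Purkinje structures, or the density and
irregularity of real human trabeculation. Passing tests therefore show
that the *mechanism* (sign pattern, make/break dependence on coupling
interval and strength, polarity asymmetry under a radial field, filament
response direction) is reproduced — not that any absolute percentage of
a human-heart simulation is.

## Protocols

Pacing: 5 uniform beats at BCL 500 ms after 2 s quiescent
equilibration; states checkpointed at coupling intervals 220–340 ms
after the last stimulus onset. A uniform monodomain tissue under a
uniform stimulus is exactly the single cell (no gradients by symmetry),
so the preconditioner's default fast path integrates one cell and
broadcasts; the full-tissue path exists and is tested against it.

Shocks: 10 ms square monophasic pulses, 1–10 V, anodal (+V on the
cavity electrode) or cathodal (−V), ground at 0; bidomain during and
after the shock with the electrode floated at shock-end. Fields are
sampled at 9 ms ("shock-end") and 20 ms ("10 ms post-shock") after
onset. A matched control (electrode floating throughout, identical
stepping) defines ΔVm; a 0 V shock is by construction identical to its
control. VE polarity statistics are reported per named surface
(endocardium, epicardium, trabecular proximal/distal faces).

Reentry: cross-field S1–S2 (the canonical stand-in, since the original
"prescribed stimulus to the refractory tail" is not fully specified):
plane wave from one edge, quadrant S2 scanned across candidate timings;
success requires sustained activity with ≥1 phase singularity (2-D) or
filament (3-D) present across three rotation periods. Shocks during the
arrhythmia are delivered at ≥4 phases 50 ms apart; filaments are
counted every 5–10 ms for 90 ms post-shock, and the anodal−cathodal
paired difference of mean counts is the reported direction.

**Desk-scale VT preset.** Sustained reentry on a few-cm domain needs a
wavelength far below the human model's ~15 cm, and the anisotropic
CV-reduced conductivities block cross-fibre conduction outright on a
500 µm reentry lattice (σ_t·s ≈ 0.05 mS/cm). The VT preset therefore
uses isotropic conductivities at scale 0.25 (CV ≈ 10 cm/s on the
lattice), accelerated repolarisation (IKr and IKs ×12 → APD90 ≈ 99 ms,
wavelength ≈ 1.1 cm inside a 2.4 cm wall) and a 0.05 ms ODE step.
These are study conditions fixed by wavelength/lattice arithmetic, not
fitted quantities; the anodal−cathodal paired-difference *direction* is
the only claim made at this scale.

## Filament detection

A tissue cell is marked when its corner values straddle both the
−20 mV Vm isosurface and the zero of the backward-difference dVm/dt
(frames 1 ms apart by default); marked cells link into filaments by
full vertex connectivity (26/8-neighbourhoods). Face-only adjacency was
rejected after the oracle suite showed it fragments filaments crossing
cells obliquely. The independent oracle is phase winding: with phase
θ = atan2(Vm(t)−V*, Vm(t−dt)−V*), plaquettes with ±2π winding host
singularities; on 20 randomised analytic spiral/scroll fields the two
methods agree exactly (counts 0/1/2/3, charges ±1).

Activation/hyperpolarisation fractions use strict thresholds
(Vm > −20 mV, Vm < −80 mV) over named node sets; "endocardium" includes
the trabecular faces for whole-surface statistics only where stated.

## Numerical choices and edge cases

* Gate-rate formulas are evaluated on voltage clamped to [−150, 250] mV
  (as tabulated tissue codes do); ohmic and augmentation terms use the
  true voltage.
* Elliptic solves are exact (sparse LU); with no Dirichlet set active a
  zero-mean gauge is applied (the pure-Neumann operator is singular).
* Degenerate geometry configurations error out rather than silently
  change topology: a "detached" trabecula with zero cleft, a trabecula
  wider than its clearance, a wall under 3 cells, a zero inner radius.
* The detachment checker demands: exactly two wall-contact clusters per
  strand, a cleft adjacent to the span, and that deleting the contact
  cells disconnects the strand — an attached ridge fails all of it.
* Determinism: identical configs reproduce outputs bit-identically on
  one platform; seeds enter only through optional trabecula placement.

## Known limitations

* First-order splitting couples the elliptic and parabolic stages
  explicitly; the equal-anisotropy identity is met at the shock step
  (0.005 ms) but degrades linearly with larger steps.
* The electrode is a Dirichlet node set (ideal voltage source); no
  electrode–electrolyte interface impedance, so computed resistances
  are geometric.
* 2-D slab runs are per-unit-depth; resistances quoted in Ω assume a
  1 cm extrusion.
* The VT preset's shortened action potential trades restitution realism
  for domain size; filament counts there are ordinal, not quantitative.
* Electroporation constants are representative, not fitted to any
  measurement; only their regime (inert below ~0.5 V, clamping near
  1 V) is load-bearing, and tests only rely on that regime.
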