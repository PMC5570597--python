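# veshock

Desk-scale bidomain simulation of how low-energy monophasic shocks
interact with *detached endocardial trabeculae* — muscular strands
attached to the ventricular wall only at their ends, with a blood-filled
cleft beneath — to form **virtual electrodes** (VEs) and a
polarity-asymmetric excitation response.

## Who this is for

Cardiac-electrophysiology modellers who want a small, fully synthetic,
reproducible testbed for shock–anatomy interaction mechanisms: VE sign
patterns at bath-separated structures, make/break excitation as a
function of coupling interval and shock strength, anodal/cathodal
asymmetry under a radial intracavitary field, and filament-count
responses of shocked reentry. Everything runs on a laptop; no meshes,
imaging data or cluster required.

## The model

Tissue follows the bidomain equations with a conductive bath,

    β Cm ∂Vm/∂t = ∇·σᵢ∇(Vm + φₑ) − β I_ion(Vm, η) + I_s
    ∇·(σᵢ+σₑ)∇φₑ = −∇·σᵢ∇Vm   (tissue),   ∇·σ_b∇φₑ = −I_eb   (bath)

with Vm = φᵢ − φₑ, Dirichlet φₑ on electrode/ground node sets, and the
monodomain reduction (harmonic-mean tensor σₘ = σᵢσₑ/(σᵢ+σₑ)) for
pacing and arrhythmia evolution. Membrane kinetics are the 2004/2006
human ventricular models (epicardial), augmented for strong shocks with
an electroporation pore current and a hypothetical outward K⁺ current
recruited beyond +160 mV. Discretisation: lumped-mass Q1 finite
elements on labelled structured grids, Rush–Larsen/implicit-diffusion
operator splitting (0.02 ms pacing / 0.005 ms shock steps), rule-based
fibres (±60° transmural inclination from a Laplace depth solve,
trabecular fibres along the strand axis). Shock energy follows
E = V²T/R with R from the discrete flux integral ∮σ_b∇φₑ·n̂ dS over the
ground electrode. See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

```bash
python examples/02_trabecula_ve.py
```

builds the standard slab (250 µm cells, 1 cm wall, a 5×0.75 mm detached
trabecula over a 0.5 mm cleft), paces it uniformly 5× at 500 ms,
delivers 5 V shocks at coupling interval 280 ms, and prints the mean
shock-induced polarisation ΔVm per surface at shock-end (9 ms):

```
=== detached trabecula ===
  anodal   mean ΔVm (mV): endo=   -5.8  prox=   -7.7  dist=  +96.4  epi= +118.1
  cathodal mean ΔVm (mV): endo= +103.8  prox=  +87.9  dist=   -8.0  epi=   -9.2

=== attached trabecula ===
  anodal   mean ΔVm (mV): endo=   -9.4  prox=   -7.7  dist=   none  epi= +118.6
  cathodal mean ΔVm (mV): endo= +117.6  prox=  +99.5  dist=   none  epi=   -9.2
```

Reading: under an anodal shock, current *leaving* the myocardium on the
wall-facing (`dist`) side of the detached strand depolarises it by
~+96 mV while the electrode-facing side (`prox`) and smooth endocardium
hyperpolarise — an isolated endocardial activation source that a smooth
wall or attached ridge (whose `dist` column reads `none`) cannot
produce. Reversing polarity flips every sign. Other examples cover the single
cell, strength–interval capture curves, resistance/energy, filament
counting, and the anodal/cathodal asymmetry in an annular cavity.

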