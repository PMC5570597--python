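"""Strong-shock membrane augmentation currents.

Shocks of a few volts polarise surface tissue far outside the range where
standard ionic models are valid.  Two augmentation currents reproduce the
asymmetric saturation of the membrane response at such polarisations:

1. An electroporation current carried by a dynamic population of membrane
   pores.  The normalised pore density ``n`` follows the asymptotic
   Smoluchowski rate equation

       dn/dt = a * exp((Vm/Vep)^2) * (1 - n * exp(-q * (Vm/Vep)^2))

   with the standard characteristic voltage Vep = 258 mV and q = 2.46,
   and the pore current is ohmic, ``I_ep = g_ep * n * Vm``.  Pore creation
   is negligible at physiological potentials (the equilibrium density at
   rest is of order one on a scale where shock-level densities reach
   hundreds) and sharply superexponential beyond a few hundred mV.

2. A hypothetical outward K+ current recruited only at large positive
   polarisations (threshold ~ +160 mV), modelled as an instantaneously
   gated sigmoidal conductance.

Constants live in one dataclass so they can be swapped wholesale; the
magnitudes are literature-representative tissue-scale values, chosen so
the currents act only at shock-level polarisations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AugmentationParams:
    # electroporation
    v_ep: float = 258.0      # characteristic pore-formation voltage (mV)
    q: float = 2.46          # pore-density equilibrium exponent
    rate: float = 5.0e-7     # a: pore creation rate scale (1/ms); with this
    #                          scale pores form within ms only beyond ~0.8 V,
    #                          and resting accumulation over seconds is
    #                          electrically negligible
    g_ep: float = 0.2        # pore conductance per unit density (mS/cm²)
    n_max: float = 1.0e3     # hard cap on normalised pore density
    # hypothetical K+ current
    g_k: float = 0.5         # conductance (mS/cm²)
    k_slope: float = 8.0     # activation slope (mV)
    k_shift: float = 20.0    # half-activation sits threshold + shift (mV)
    e_k: float = -86.0       # reversal potential (mV)


DEFAULT = AugmentationParams()


def electroporation_current(Vm, n_pore, p: AugmentationParams = DEFAULT):
    """Ohmic pore current (µA/cm², outward positive for Vm > 0)."""
    return p.g_ep * n_pore * Vm


def step_pore_density(Vm, n_pore, dt: float, p: AugmentationParams = DEFAULT):
    """Advance normalised pore density by one explicit step."""
    x = np.clip((np.asarray(Vm, dtype=float) / p.v_ep) ** 2, 0.0, 50.0)
    dn = p.rate * np.exp(x) * (1.0 - n_pore * np.exp(-p.q * x))
    return np.clip(n_pore + dt * dn, 0.0, p.n_max)


def k_aug_current(Vm, threshold: float = 160.0,
                  p: AugmentationParams = DEFAULT):
    """Outward K+ current active only beyond ~`threshold` mV."""
    gate = 1.0 / (1.0 + np.exp(-(np.asarray(Vm, dtype=float)
                                 - (threshold + p.k_shift)) / p.k_slope))
    return p.g_k * gate * (Vm - p.e_k)


def augmentation_currents(Vm, n_pore, threshold: float = 160.0,
                          electroporation: bool = True, k_current: bool = True,
                          p: AugmentationParams = DEFAULT):
    """Total augmentation current density (µA/cm²)."""
    total = np.zeros_like(np.asarray(Vm, dtype=float))
    if electroporation:
        total = total + electroporation_current(Vm, n_pore, p)
    if k_current:
        total = total + k_aug_current(Vm, threshold, p)
    return total
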