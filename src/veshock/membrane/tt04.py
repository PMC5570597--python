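"""2004 ten Tusscher-Noble-Noble-Panfilov human ventricular model (epicardial).

The predecessor of the 2006 formulation: single cytosolic calcium pool
with a calcium-gated L-type inactivation (fCa) and a voltage/calcium
release gate (g) instead of the 2006 dyadic-subspace scheme.  Kept as a
selectable variant because the two published generations differ visibly
in rate adaptation: at a 500 ms cycle length this model repolarises
earlier in late phase 3, which matters when reading the membrane state at
short coupling intervals.

Same interface, units and augmentation handling as
:class:`veshock.membrane.tp06.TP06Model`.
"""
from __future__ import annotations

import numpy as np

from . import augment
from .base import MembraneParams, check_vm, rush_larsen
from .tp06 import (R_GAS, FARADAY, TEMP, RTONF, KO, NAO, CAO, TP06Model)

VC, VSR = 0.016404, 0.001094
CAPACITANCE = 0.185

BUFC, KBUFC = 0.15, 0.001
BUFSR, KBUFSR = 10.0, 0.3

VMAXUP, KUP = 0.000425, 0.00025
AREL, BREL, CREL = 0.016464, 0.25, 0.008232
VLEAK = 8.0e-5
TAU_G = 2.0
TAU_FCA = 2.0

GNA = 14.838
GK1 = 5.405
GTO = 0.294          # epicardial
GKR = 0.096
GKS = 0.245          # epicardial
GCAL = 1.75e-4
GBNA = 0.00029
GBCA = 0.000592
GPCA = 0.825
KPCA = 0.0005
GPK = 0.0146
PKNA = 0.03
KNAK, KMK, KMNA = 1.362, 1.0, 40.0
KNACA, KMNAI, KMCA, KSAT, GAMMA = 1000.0, 87.5, 1.38, 0.1, 0.35

INITIAL = {
    "cai": 0.0002, "casr": 0.2, "nai": 11.6, "ki": 138.3,
    "m": 0.0, "h": 0.75, "j": 0.75, "xr1": 0.0, "xr2": 1.0, "xs": 0.0,
    "r": 0.0, "s": 1.0, "d": 0.0, "f": 1.0, "fca": 1.0, "g": 1.0,
    "n_pore": 0.0,
}
V_INIT = -86.2


class TT04Model(TP06Model):
    """Epicardial 2004 human ventricular membrane, optionally augmented."""

    name = "human_ventricular_2004_augmented"

    def __init__(self, params: MembraneParams | None = None,
                 aug_params: augment.AugmentationParams | None = None):
        super().__init__(params, aug_params)
        s = self.params.scales
        self.gkr = GKR * s.get("g_kr", 1.0)
        self.gks = GKS * s.get("g_ks", 1.0)
        self.gto = GTO * s.get("g_to", 1.0)
        self.gcal = GCAL * s.get("g_cal", 1.0)

    def initial_state(self, n: int) -> dict[str, np.ndarray]:
        return {k: np.full(n, v, dtype=float) for k, v in INITIAL.items()}

    def initial_vm(self, n: int) -> np.ndarray:
        return np.full(n, V_INIT, dtype=float)

    # ------------------------------------------------------------------
    def step(self, Vm, state, dt: float, stim=0.0):
        if dt <= 0:
            raise ValueError("dt must be positive")
        check_vm(Vm)
        V = np.asarray(Vm, dtype=float)
        with np.errstate(over="ignore"):
            I, gates = self._currents(V, state)

        for g, (ginf, gtau) in gates.items():
            state[g] = rush_larsen(state[g], ginf, gtau, dt)
        self._step_gated(V, state, dt)
        self._step_calcium(V, state, I, dt)

        inv_vcf = 1.0 / (VC * FARADAY)
        state["nai"] = state["nai"] - dt * (
            I["na"] + I["bna"] + 3.0 * I["nak"] + 3.0 * I["naca"]
        ) * inv_vcf * CAPACITANCE
        state["ki"] = state["ki"] - dt * (
            -stim + I["k1"] + I["to"] + I["kr"] + I["ks"]
            - 2.0 * I["nak"] + I["pk"]
        ) * inv_vcf * CAPACITANCE

        if self.params.electroporation:
            state["n_pore"] = augment.step_pore_density(V, state["n_pore"],
                                                        dt, self.aug)
        return I["total"]

    # ------------------------------------------------------------------
    def _currents(self, V, st):
        exp = np.exp
        ek = RTONF * np.log(KO / st["ki"])
        ena = RTONF * np.log(NAO / st["nai"])
        eks = RTONF * np.log((KO + PKNA * NAO) / (st["ki"] + PKNA * st["nai"]))
        eca = 0.5 * RTONF * np.log(CAO / st["cai"])

        ak1 = 0.1 / (1.0 + exp(0.06 * (V - ek - 200.0)))
        bk1 = (3.0 * exp(0.0002 * (V - ek + 100.0)) + exp(0.1 * (V - ek - 10.0))) \
            / (1.0 + exp(-0.5 * (V - ek)))
        i_k1 = GK1 * ak1 / (ak1 + bk1) * (V - ek)

        i_to = self.gto * st["r"] * st["s"] * (V - ek)
        i_kr = self.gkr * np.sqrt(KO / 5.4) * st["xr1"] * st["xr2"] * (V - ek)
        i_ks = self.gks * st["xs"] ** 2 * (V - eks)
        i_na = GNA * st["m"] ** 3 * st["h"] * st["j"] * (V - ena)
        i_bna = GBNA * (V - ena)

        expv = exp(np.clip(2.0 * V / RTONF, -200.0, 200.0))
        denom = np.where(np.abs(expv - 1.0) < 1e-9, 1e-9, expv - 1.0)
        i_cal = self.gcal * st["d"] * st["f"] * st["fca"] \
            * 4.0 * V * FARADAY / RTONF \
            * (st["cai"] * expv - 0.341 * CAO) / denom
        i_bca = GBCA * (V - eca)

        i_nak = KNAK * (KO / (KO + KMK)) * (st["nai"] / (st["nai"] + KMNA)) \
            / (1.0 + 0.1245 * exp(-0.1 * V / RTONF) + 0.0353 * exp(-V / RTONF))
        i_naca = KNACA / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
                          * (1.0 + KSAT * exp((GAMMA - 1.0) * V / RTONF))) \
            * (exp(GAMMA * V / RTONF) * st["nai"] ** 3 * CAO
               - exp((GAMMA - 1.0) * V / RTONF) * NAO ** 3 * st["cai"] * 2.5)
        i_pca = GPCA * st["cai"] / (KPCA + st["cai"])
        i_pk = GPK * (V - ek) / (1.0 + exp((25.0 - V) / 5.98))

        total = (i_k1 + i_to + i_kr + i_ks + i_cal + i_nak + i_na + i_bna
                 + i_naca + i_bca + i_pk + i_pca)
        p = self.params
        if p.electroporation or p.k_current:
            total = total + augment.augmentation_currents(
                V, st["n_pore"], p.k_aug_threshold,
                p.electroporation, p.k_current, self.aug)

        I = dict(k1=i_k1, to=i_to, kr=i_kr, ks=i_ks, cal=i_cal, nak=i_nak,
                 na=i_na, bna=i_bna, naca=i_naca, bca=i_bca, pk=i_pk,
                 pca=i_pca, total=total)
        return I, self._gate_rates(V, st)

    @staticmethod
    def _gate_rates(V, st):
        V = np.clip(V, -150.0, 250.0)
        exp = np.exp
        g = {}

        m_inf = 1.0 / (1.0 + exp((-56.86 - V) / 9.03)) ** 2
        am = 1.0 / (1.0 + exp((-60.0 - V) / 5.0))
        bm = 0.1 / (1.0 + exp((V + 35.0) / 5.0)) \
            + 0.1 / (1.0 + exp((V - 50.0) / 200.0))
        g["m"] = (m_inf, am * bm)

        h_inf = 1.0 / (1.0 + exp((V + 71.55) / 7.43)) ** 2
        lo = V < -40.0
        ah = np.where(lo, 0.057 * exp(-(V + 80.0) / 6.8), 0.0)
        bh = np.where(lo,
                      2.7 * exp(0.079 * V) + 3.1e5 * exp(0.3485 * V),
                      0.77 / (0.13 * (1.0 + exp(-(V + 10.66) / 11.1))))
        g["h"] = (h_inf, 1.0 / (ah + bh))
        aj = np.where(lo,
                      (-2.5428e4 * exp(0.2444 * V) - 6.948e-6 * exp(-0.04391 * V))
                      * (V + 37.78) / (1.0 + exp(0.311 * (V + 79.23))),
                      0.0)
        bj = np.where(lo,
                      0.02424 * exp(-0.01052 * V)
                      / (1.0 + exp(-0.1378 * (V + 40.14))),
                      0.6 * exp(0.057 * V) / (1.0 + exp(-0.1 * (V + 32.0))))
        g["j"] = (h_inf, 1.0 / (aj + bj))

        xr1_inf = 1.0 / (1.0 + exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + exp((V + 30.0) / 11.5))
        g["xr1"] = (xr1_inf, axr1 * bxr1)

        xr2_inf = 1.0 / (1.0 + exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + exp((V - 60.0) / 20.0))
        g["xr2"] = (xr2_inf, axr2 * bxr2)

        xs_inf = 1.0 / (1.0 + exp((-5.0 - V) / 14.0))
        axs = 1100.0 / np.sqrt(1.0 + exp((-10.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + exp((V - 60.0) / 20.0))
        g["xs"] = (xs_inf, axs * bxs)

        r_inf = 1.0 / (1.0 + exp((20.0 - V) / 6.0))
        g["r"] = (r_inf, 9.5 * exp(-(V + 40.0) ** 2 / 1800.0) + 0.8)
        s_inf = 1.0 / (1.0 + exp((V + 20.0) / 5.0))
        g["s"] = (s_inf, 85.0 * exp(-(V + 45.0) ** 2 / 320.0)
                  + 5.0 / (1.0 + exp((V - 20.0) / 5.0)) + 3.0)

        d_inf = 1.0 / (1.0 + exp((-5.0 - V) / 7.5))
        ad = 1.4 / (1.0 + exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + exp((V + 5.0) / 5.0))
        cd = 1.0 / (1.0 + exp((50.0 - V) / 20.0))
        g["d"] = (d_inf, ad * bd + cd)

        f_inf = 1.0 / (1.0 + exp((V + 20.0) / 7.0))
        tauf = 1125.0 * exp(-(V + 27.0) ** 2 / 240.0) + 80.0 \
            + 165.0 / (1.0 + exp((25.0 - V) / 10.0))
        g["f"] = (f_inf, tauf)
        return g

    def _step_gated(self, V, st, dt):
        """fCa and g: first-order gates frozen during depolarised upstrokes."""
        cai = st["cai"]
        alpha = 1.0 / (1.0 + (cai / 0.000325) ** 8)
        beta = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
        gama = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
        fca_inf = (alpha + beta + gama + 0.23) / 1.46
        fca_new = rush_larsen(st["fca"], fca_inf, TAU_FCA, dt)
        freeze = (fca_new > st["fca"]) & (V > -60.0)
        st["fca"] = np.where(freeze, st["fca"], fca_new)

        g_inf = np.where(cai < 0.00035,
                         1.0 / (1.0 + (cai / 0.00035) ** 6),
                         1.0 / (1.0 + (cai / 0.00035) ** 16))
        g_new = rush_larsen(st["g"], g_inf, TAU_G, dt)
        freeze = (g_new > st["g"]) & (V > -60.0)
        st["g"] = np.where(freeze, st["g"], g_new)

    def _step_calcium(self, V, st, I, dt):
        i_rel = st["d"] * st["g"] * (CREL + AREL * st["casr"] ** 2
                                     / (BREL ** 2 + st["casr"] ** 2))
        i_leak = VLEAK * (st["casr"] - st["cai"])
        i_up = VMAXUP / (1.0 + (KUP / st["cai"]) ** 2)

        inv_vcf2 = 1.0 / (2.0 * VC * FARADAY)

        casq = BUFSR * st["casr"] / (st["casr"] + KBUFSR)
        dsr = dt * (VC / VSR) * (-i_rel + i_up - i_leak)
        b = BUFSR - casq - dsr - st["casr"] + KBUFSR
        c = KBUFSR * (casq + dsr + st["casr"])
        st["casr"] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

        cab = BUFC * st["cai"] / (st["cai"] + KBUFC)
        dca = dt * (-(I["cal"] + I["bca"] + I["pca"] - 2.0 * I["naca"])
                    * inv_vcf2 * CAPACITANCE + i_rel - i_up + i_leak)
        b = BUFC - cab - dca - st["cai"] + KBUFC
        c = KBUFC * (cab + dca + st["cai"])
        st["cai"] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0
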