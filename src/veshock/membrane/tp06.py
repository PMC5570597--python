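"""Human ventricular ionic membrane model (epicardial variant).

Vectorised implementation of the 2006 ten Tusscher-Panfilov human
ventricular cell model: fast/late Na+, L-type Ca2+ with subspace calcium,
transient outward, rapid/slow delayed rectifier and inward rectifier K+
currents, Na+/K+ pump, Na+/Ca2+ exchanger, sarcolemmal/background Ca2+
handling and a CICR sarcoplasmic-reticulum release with dyadic-subspace
gating.  Units follow the published formulation: mV, ms, mM; current
densities in pA/pF which, with Cm = 1 µF/cm², are numerically µA/cm².

The epicardial parameter set is used uniformly (no transmural cell-type
heterogeneity).  Optional conductance multipliers (``MembraneParams.scales``,
keys ``g_ks``/``g_kr``/``g_cal``/...) support desk-scale variants such as
the shortened-action-potential preset used for reentry studies.

Gates advance by Rush-Larsen exponential updates; intracellular calcium
buffering uses the steady-state (instantaneous buffer) quadratic update of
the published code.  The shock augmentation currents of
:mod:`veshock.membrane.augment` are added when enabled.
"""
from __future__ import annotations

import numpy as np

from . import augment
from .base import MembraneParams, check_vm, rush_larsen

# physical constants
R_GAS = 8314.472     # mJ/(mol K)
FARADAY = 96485.3415  # C/mol
TEMP = 310.0
RTONF = R_GAS * TEMP / FARADAY

# external concentrations (mM)
KO, NAO, CAO = 5.4, 140.0, 2.0

# cell geometry (volumes in µm³-scaled units of the published code)
VC, VSR, VSS = 0.016404, 0.001094, 0.00005468
CAPACITANCE = 0.185

# buffering
BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025

# SR calcium handling
VMAXUP, KUP = 0.006375, 0.00025
VREL, K1P, K2P, K3, K4 = 0.102, 0.15, 0.045, 0.060, 0.005
EC, MAXSR, MINSR = 1.5, 2.5, 1.0
VLEAK, VXFER = 0.00036, 0.0038

# conductances (epicardial)
GNA = 14.838
GK1 = 5.405
GTO = 0.294
GKR = 0.153
GKS = 0.392
GCAL = 3.980e-5
GBNA = 0.00029
GBCA = 0.000592
GPCA = 0.1238
KPCA = 0.0005
GPK = 0.0146
PKNA = 0.03
KNAK, KMK, KMNA = 2.724, 1.0, 40.0
KNACA, KMNAI, KMCA, KSAT, GAMMA = 1000.0, 87.5, 1.38, 0.1, 0.35

#: published initial conditions (quiescent, near-resting)
INITIAL = {
    "cai": 0.00007, "casr": 1.3, "cass": 0.00007, "nai": 7.67, "ki": 138.3,
    "m": 0.0, "h": 0.75, "j": 0.75, "xr1": 0.0, "xr2": 1.0, "xs": 0.0,
    "r": 0.0, "s": 1.0, "d": 0.0, "f": 1.0, "f2": 1.0, "fcass": 1.0,
    "rbar": 1.0, "n_pore": 0.0,
}
V_INIT = -86.2


class TP06Model:
    """Epicardial human ventricular membrane, optionally shock-augmented."""

    name = "human_ventricular_augmented"

    def __init__(self, params: MembraneParams | None = None,
                 aug_params: augment.AugmentationParams | None = None):
        self.params = params or MembraneParams()
        self.aug = aug_params or augment.DEFAULT
        s = self.params.scales
        self.gna = GNA * s.get("g_na", 1.0)
        self.gto = GTO * s.get("g_to", 1.0)
        self.gkr = GKR * s.get("g_kr", 1.0)
        self.gks = GKS * s.get("g_ks", 1.0)
        self.gk1 = GK1 * s.get("g_k1", 1.0)
        self.gcal = GCAL * s.get("g_cal", 1.0)

    # ------------------------------------------------------------------
    def initial_state(self, n: int) -> dict[str, np.ndarray]:
        return {k: np.full(n, v, dtype=float) for k, v in INITIAL.items()}

    def initial_vm(self, n: int) -> np.ndarray:
        return np.full(n, V_INIT, dtype=float)

    # ------------------------------------------------------------------
    def ionic_current(self, Vm, state):
        """Total ionic current (µA/cm²) without advancing the state."""
        check_vm(Vm)
        with np.errstate(over="ignore"):
            I, _ = self._currents(np.asarray(Vm, dtype=float), state)
        return I["total"]

    def step(self, Vm, state, dt: float, stim=0.0):
        """Advance gates/concentrations by ``dt``; return I_ion (µA/cm²).

        ``stim`` (µA/cm², depolarising positive) only enters the K+
        bookkeeping, mirroring the published code; the caller applies it
        to Vm.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        check_vm(Vm)
        V = np.asarray(Vm, dtype=float)
        with np.errstate(over="ignore"):
            I, gates = self._currents(V, state)

        for g, (ginf, gtau) in gates.items():
            state[g] = rush_larsen(state[g], ginf, gtau, dt)

        self._step_calcium(V, state, I, dt)

        inv_vcf = 1.0 / (VC * FARADAY)
        state["nai"] = state["nai"] - dt * (
            I["na"] + I["bna"] + 3.0 * I["nak"] + 3.0 * I["naca"]
        ) * inv_vcf * CAPACITANCE
        state["ki"] = state["ki"] - dt * (
            -stim + I["k1"] + I["to"] + I["kr"] + I["ks"]
            - 2.0 * I["nak"] + I["pk"]
        ) * inv_vcf * CAPACITANCE

        p = self.params
        if p.electroporation:
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
        i_k1 = self.gk1 * ak1 / (ak1 + bk1) * (V - ek)

        i_to = self.gto * st["r"] * st["s"] * (V - ek)
        i_kr = self.gkr * np.sqrt(KO / 5.4) * st["xr1"] * st["xr2"] * (V - ek)
        i_ks = self.gks * st["xs"] ** 2 * (V - eks)
        i_na = self.gna * st["m"] ** 3 * st["h"] * st["j"] * (V - ena)
        i_bna = GBNA * (V - ena)

        vshift = V - 15.0
        expv = exp(np.clip(2.0 * vshift / RTONF, -200.0, 200.0))
        # L'Hopital-safe driving term at V = 15 mV
        denom = np.where(np.abs(expv - 1.0) < 1e-9, 1e-9, expv - 1.0)
        i_cal = self.gcal * st["d"] * st["f"] * st["f2"] * st["fcass"] \
            * 4.0 * vshift * FARADAY / RTONF \
            * (0.25 * st["cass"] * expv - CAO) / denom
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
        # rate formulas are evaluated on a clamped voltage, as tabulated
        # tissue codes do; shock-level excursions keep the true V in the
        # ohmic/augmentation terms but saturate the kinetics.
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
        axs = 1400.0 / np.sqrt(1.0 + exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + exp((V - 35.0) / 15.0))
        g["xs"] = (xs_inf, axs * bxs + 80.0)

        # epicardial transient-outward kinetics
        r_inf = 1.0 / (1.0 + exp((20.0 - V) / 6.0))
        g["r"] = (r_inf, 9.5 * exp(-(V + 40.0) ** 2 / 1800.0) + 0.8)
        s_inf = 1.0 / (1.0 + exp((V + 20.0) / 5.0))
        g["s"] = (s_inf, 85.0 * exp(-(V + 45.0) ** 2 / 320.0)
                  + 5.0 / (1.0 + exp((V - 20.0) / 5.0)) + 3.0)

        d_inf = 1.0 / (1.0 + exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + exp((V + 5.0) / 5.0))
        cd = 1.0 / (1.0 + exp((50.0 - V) / 20.0))
        g["d"] = (d_inf, ad * bd + cd)

        f_inf = 1.0 / (1.0 + exp((V + 20.0) / 7.0))
        af = 1102.5 * exp(-((V + 27.0) ** 2) / 225.0)
        bf = 200.0 / (1.0 + exp((13.0 - V) / 10.0))
        cf = 180.0 / (1.0 + exp((V + 30.0) / 10.0)) + 20.0
        g["f"] = (f_inf, af + bf + cf)

        f2_inf = 0.67 / (1.0 + exp((V + 35.0) / 7.0)) + 0.33
        af2 = 600.0 * exp(-(V + 25.0) ** 2 / 170.0)
        bf2 = 31.0 / (1.0 + exp((25.0 - V) / 10.0))
        cf2 = 16.0 / (1.0 + exp((V + 30.0) / 10.0))
        g["f2"] = (f2_inf, af2 + bf2 + cf2)

        fcass_inf = 0.6 / (1.0 + (st["cass"] / 0.05) ** 2) + 0.4
        g["fcass"] = (fcass_inf, 80.0 / (1.0 + (st["cass"] / 0.05) ** 2) + 2.0)
        return g

    def _step_calcium(self, V, st, I, dt):
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / st["casr"]) ** 2)
        k1 = K1P / kcasr
        k2 = K2P * kcasr
        # SR release gate: linear ODE in rbar -> exponential update
        tau_r = 1.0 / (K4 + k2 * st["cass"])
        rbar_inf = K4 * tau_r
        st["rbar"] = rbar_inf + (st["rbar"] - rbar_inf) * np.exp(-dt / tau_r)
        oo = k1 * st["cass"] ** 2 * st["rbar"] / (K3 + k1 * st["cass"] ** 2)

        i_rel = VREL * oo * (st["casr"] - st["cass"])
        i_leak = VLEAK * (st["casr"] - st["cai"])
        i_up = VMAXUP / (1.0 + (KUP / st["cai"]) ** 2)
        i_xfer = VXFER * (st["cass"] - st["cai"])

        inv_vcf2 = 1.0 / (2.0 * VC * FARADAY)
        inv_vssf2 = 1.0 / (2.0 * VSS * FARADAY)

        # instantaneous-buffer quadratic updates (published scheme)
        casq = BUFSR * st["casr"] / (st["casr"] + KBUFSR)
        dsr = dt * (i_up - i_rel - i_leak)
        b = BUFSR - casq - dsr - st["casr"] + KBUFSR
        c = KBUFSR * (casq + dsr + st["casr"])
        st["casr"] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

        cssb = BUFSS * st["cass"] / (st["cass"] + KBUFSS)
        dss = dt * (-i_xfer * (VC / VSS) + i_rel * (VSR / VSS)
                    - I["cal"] * inv_vssf2 * CAPACITANCE)
        b = BUFSS - cssb - dss - st["cass"] + KBUFSS
        c = KBUFSS * (cssb + dss + st["cass"])
        st["cass"] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

        cab = BUFC * st["cai"] / (st["cai"] + KBUFC)
        dca = dt * (-(I["bca"] + I["pca"] - 2.0 * I["naca"])
                    * inv_vcf2 * CAPACITANCE
                    - (i_up - i_leak) * (VSR / VC) + i_xfer)
        b = BUFC - cab - dca - st["cai"] + KBUFC
        c = KBUFC * (cab + dca + st["cai"])
        st["cai"] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0
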