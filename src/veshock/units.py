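"""Internal unit system and conversion helpers.

All tissue-scale computations use one consistent unit set:

==============  =========  =====================================
quantity        unit       note
==============  =========  =====================================
potential       mV
time            ms
length          cm         grid spacing is configured in µm
conductivity    mS/cm      1 S/m = 10 mS/cm
capacitance     µF/cm²
membrane I      µA/cm²
volume I        µA/cm³     transmembrane stimuli, β·I_m
β (S:V ratio)   1/cm
==============  =========  =====================================

With these units the parabolic bidomain balance
``β·Cm·∂Vm/∂t = ∇·σ∇V − β·I_ion + I_s`` is dimensionally consistent
term-by-term (each term is µA/cm³) with no hidden prefactors.
"""

UM_PER_CM = 1.0e4

#: 1 S/m expressed in mS/cm.
S_PER_M_TO_MS_PER_CM = 10.0

#: membrane surface-to-volume ratio (1/cm); standard bidomain value.
BETA = 1400.0

#: membrane capacitance per unit area (µF/cm²).
CM = 1.0

#: applied electrode voltages are configured in volts.
V_TO_MV = 1000.0


def um_to_cm(x_um: float) -> float:
    return x_um / UM_PER_CM


def s_per_m_to_ms_per_cm(sigma: float) -> float:
    return sigma * S_PER_M_TO_MS_PER_CM
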