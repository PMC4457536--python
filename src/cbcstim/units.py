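"""Physical constants and the frozen unit system.

Everything in the package uses one consistent unit system chosen so that the
cable equation needs no hidden conversion factors:

================  ========
quantity          unit
================  ========
voltage           mV
time              ms
length            um
resistance        kOhm
capacitance       uF
conductance       mS  (= 1/kOhm)
current           uA
current density   uA/cm^2
specific cond.    mS/cm^2
concentration     uM
================  ========

With these units ``dV/dt = I / C`` is mV/ms = uA/uF, and a specific
conductance in mS/cm^2 times a driving force in mV is a current density in
uA/cm^2.
"""

# membrane constants
CM_UF_PER_CM2 = 1.1        # specific membrane capacitance
RHO_AXIAL_OHM_CM = 130.0   # cytoplasmic axial resistivity
E_LEAK_MV = -53.08         # leak reversal = resting potential
G_LEAK_MS_PER_CM2 = 0.0417
V_REST_MV = E_LEAK_MV

# calcium bookkeeping
FARADAY_C_PER_MOL = 96489.0
GAS_CONSTANT = 8.31446     # J / (mol K)
TEMPERATURE_K = 298.15     # experiments were run at 25 C
# RT/2F in mV (divalent ion)
RT_2F_MV = 1e3 * GAS_CONSTANT * TEMPERATURE_K / (2.0 * FARADAY_C_PER_MOL)

CA_RES_UM = 0.15           # residual intracellular Ca++ (uM)
CA_TAU_MS = 1.5            # Ca++ extrusion time constant
CA_OUT_UM = 1800.0         # extracellular Ca++, held constant

# d[Ca]/dt in uM/ms equals  CA_FLUX_FACTOR * (s/v)[1/um] * i[uA/cm^2] / (2F)
# (derived by converting s/v to 1/m and i to A/m^2: mol m^-3 s^-1 == uM/ms)
CA_FLUX_FACTOR = 1.0e4

# geometry conversions
UM2_TO_CM2 = 1.0e-8
OHM_CM_TO_OHM_UM = 1.0e4
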