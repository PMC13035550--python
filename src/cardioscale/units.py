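"""Unit conventions and conversion constants.

Internal conventions
--------------------
time        s
pressure    mmHg at interfaces, kPa inside stress computations
stress      kPa
length      um for sarcomeres, cm for ventricular geometry
volume      mL internally, uL at I/O
compliance  mL/mmHg (reported also in cm^3/kPa)
resistance  mmHg s/mL
concentration  uM (calcium and metabolites)
"""

KPA_PER_MMHG = 0.1333223684  # 101.325 kPa / 760 mmHg
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG

UL_PER_ML = 1000.0
ML_PER_UL = 1.0e-3

# compliance unit conversion: (mL/mmHg) * MMHG_PER_KPA = cm^3/kPa
CM3_PER_KPA_PER_ML_PER_MMHG = MMHG_PER_KPA

# power intensity: 1 kPa*um/s = 1e3 Pa * 1e-6 m / s = 1e-3 W/m^2
W_PER_M2_PER_KPA_UM_S = 1.0e-3
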