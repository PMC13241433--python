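"""Unit conversions.

The package works internally in an mm-N-s system: lengths in mm, forces in
N, stresses in MPa (N/mm^2), permeability in mm^4/(N*s), flow rate per unit
axial length in mm^2/s.  Transmural pressures are accepted in mmHg (the unit
of pressure-inflation protocols) and moduli in kPa; stresses are reported in
kPa.
"""

#: 1 mmHg in MPa (133.322 Pa)
MMHG_TO_MPA = 1.33322e-4

#: 1 kPa in MPa
KPA_TO_MPA = 1.0e-3


def mmhg_to_mpa(p):
    return p * MMHG_TO_MPA


def mpa_to_mmhg(p):
    return p / MMHG_TO_MPA


def kpa_to_mpa(s):
    return s * KPA_TO_MPA


def mpa_to_kpa(s):
    return s / KPA_TO_MPA
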