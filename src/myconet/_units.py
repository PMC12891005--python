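"""Package-wide unit conventions and conversion constants.

Every quantity in the package uses a fixed unit convention:

========================  =====================
quantity                  unit
========================  =====================
edge length, radius       micrometre (um)
node coordinates          millimetre (mm)
areas (hull, surface)     mm^2
volumes                   mm^3 (totals), um^3 (per element)
time                      hour (h)
masses (C, P)             microgram (ug)
P uptake coefficient J    ng mm^-2 h^-1
concentrations            ug/mL
========================  =====================

All conversions between these go through the constants below; no module
hard-codes a power of ten.
"""

UM_PER_MM = 1e3
MM_PER_UM = 1e-3
UM2_PER_MM2 = 1e6
MM2_PER_UM2 = 1e-6
UM3_PER_MM3 = 1e9
MM3_PER_UM3 = 1e-9
NG_PER_UG = 1e3
UG_PER_NG = 1e-3
MM3_PER_ML = 1e3
ML_PER_MM3 = 1e-3
HOURS_PER_DAY = 24.0

# 1 ug/mL == 1 ng/mm^3 (used when coupling concentration fields to uptake
# rates expressed in ng mm^-2 h^-1)
NG_PER_MM3_PER_UG_PER_ML = 1.0
UG_PER_MM3_PER_UG_PER_ML = 1e-3

# Standard atomic masses (g/mol), CIAAW conventional values
ATOMIC_MASS_P = 30.973761998
ATOMIC_MASS_K = 39.0983
ATOMIC_MASS_H = 1.008
ATOMIC_MASS_O = 15.999

MOLAR_MASS_KH2PO4 = ATOMIC_MASS_K + 2 * ATOMIC_MASS_H + ATOMIC_MASS_P + 4 * ATOMIC_MASS_O
#: mass fraction of phosphorus in KH2PO4 (~0.2276)
P_MASS_FRACTION_KH2PO4 = ATOMIC_MASS_P / MOLAR_MASS_KH2PO4
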