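"""Physical constants and the bundled element scattering-length table.

Neutron coherent scattering lengths are the standard Sears tabulation
(values in fm); electron counts are atomic numbers. Units used throughout
the package: lengths in Å, volumes in Å³, scattering length densities in
Å⁻², intensities in cm⁻¹.
"""

from __future__ import annotations

# classical electron radius (Thomson scattering length), Å
R_ELECTRON = 2.8179403262e-5

# fm -> Å
FM_TO_ANGSTROM = 1.0e-5

# (Å/cm)² — converts |amplitude|² from Å² to cm² for absolute-scale I(q)
ANGSTROM2_TO_CM2 = 1.0e-16

#: element -> (coherent neutron scattering length b_c in fm, electron count Z)
ELEMENT_TABLE: dict[str, tuple[float, int]] = {
    "H": (-3.7390, 1),
    "D": (6.671, 1),
    "C": (6.6460, 6),
    "N": (9.36, 7),
    "O": (5.803, 8),
    "P": (5.13, 15),
    "S": (2.847, 16),
    "Na": (3.63, 11),
    "Cl": (9.5770, 17),
    "K": (3.67, 19),
    "Cu": (7.718, 29),
}

# water molecular volume, Å³ (liquid water at 20 °C, per molecule)
V_WATER = 30.0

# 64Cu physical half-life, hours.  The commonly quoted rounded value is the
# package default; the evaluated value is available for callers that want it.
CU64_HALF_LIFE_H = 12.7
CU64_HALF_LIFE_H_EVALUATED = 12.7007
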