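"""Physical constants used throughout the package.

Values follow CODATA 2018 at the precision relevant for photon transport
in the 10 keV - 1.4 MeV range.
"""

#: Electron rest energy (MeV).
ELECTRON_REST_MEV = 0.51099895

#: Classical electron radius (cm).
R_E_CM = 2.8179403262e-13

#: Avogadro constant (1/mol).
N_AVOGADRO = 6.02214076e23

#: MeV -> J conversion.
MEV_TO_J = 1.602176634e-13

#: Barn -> cm^2.
BARN_TO_CM2 = 1.0e-24

#: Standard atomic weights (g/mol) for the elements appearing in the
#: bundled material library.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Na": 22.990,
    "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078, "Ti": 47.867,
    "V": 50.942, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Ni": 58.693,
    "Zn": 65.38, "Mo": 95.95, "Ir": 192.217,
}

#: Atomic numbers for the same element set.
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "Al": 13,
    "Si": 14, "P": 15, "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20,
    "Ti": 22, "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Ni": 28, "Zn": 30,
    "Mo": 42, "Ir": 77,
}

#: K-shell binding energies (MeV) for elements whose K edge falls inside
#: the 10 keV - 1.4 MeV table range.
K_EDGES_MEV = {"Mo": 0.020000, "Ir": 0.076111}
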