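"""Physical constants and unit conversions.

Internal working units are Hartree atomic units (energies in Hartree,
lengths in bohr).  All user-facing I/O uses eV and Angstrom.
"""

HARTREE_TO_EV = 27.211386
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# Nuclear charges of the elements handled by the built-in basis library.
ELEMENT_Z = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
}

Z_ELEMENT = {z: sym for sym, z in ELEMENT_Z.items()}

# Elements of the B-Ne row: these possess a 1s core orbital that is either an
# active core (probed K-edge) or frozen in the correlated treatment.
FIRST_ROW_CORE_ELEMENTS = frozenset({"B", "C", "N", "O", "F", "Ne"})
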