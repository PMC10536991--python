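"""Unit constants.

Lengths are angstrom at every I/O boundary and bohr internally; energies are
hartree internally with kcal/mol used only for reporting.
"""

ANGSTROM_TO_BOHR = 1.8897259886
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR
HARTREE_TO_KCAL = 627.509474
HARTREE_TO_EV = 27.211386245988
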