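"""Element data for the minimal valence basis.

H carries a single s shell; first-row elements carry s and p valence shells.
Occupancies are the neutral-atom valence shell fillings used as the Mulliken
reference in the charge-fluctuation definition.
"""

from __future__ import annotations

SUPPORTED_ELEMENTS = (1, 6, 7, 8)

SYMBOLS = {1: "H", 6: "C", 7: "N", 8: "O"}
NUMBERS = {s: z for z, s in SYMBOLS.items()}

#: valence electron count per element
VALENCE_ELECTRONS = {1: 1, 6: 4, 7: 5, 8: 6}

#: angular momenta of the valence shells, in order
SHELLS = {1: ("s",), 6: ("s", "p"), 7: ("s", "p"), 8: ("s", "p")}

#: neutral-atom valence occupancy per (element, shell)
NEUTRAL_OCCUPANCY = {
    (1, "s"): 1.0,
    (6, "s"): 2.0, (6, "p"): 2.0,
    (7, "s"): 2.0, (7, "p"): 3.0,
    (8, "s"): 2.0, (8, "p"): 4.0,
}

#: orbitals per shell label
SHELL_DIM = {"s": 1, "p": 3}


def symbol(z: int) -> str:
    try:
        return SYMBOLS[z]
    except KeyError:
        raise ValueError(f"unsupported element Z={z}; supported: H,C,N,O") from None


def atomic_number(sym: str) -> int:
    try:
        return NUMBERS[sym.capitalize()]
    except KeyError:
        raise ValueError(f"unsupported element symbol {sym!r}; supported: H,C,N,O") from None


def n_orbitals(z: int) -> int:
    return sum(SHELL_DIM[l] for l in SHELLS[z])
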