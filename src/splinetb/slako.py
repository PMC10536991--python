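"""Slater-Koster transformation and molecular matrix assembly.

Two-center integrals are tabulated in the bond-aligned frame as sigma/pi
channels; `sk_pair_block` rotates them into the molecular Cartesian frame
with the standard direction-cosine rules for s/p orbitals.  Orbital ordering
is s, px, py, pz per atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .elements import SHELLS, SHELL_DIM, n_orbitals, VALENCE_ELECTRONS
from .geometry import Geometry
from .params import ParameterSet

#: how far below r_low extrapolation proceeds without complaint, angstrom
EXTRAPOLATION_GUARD = 0.05


@dataclass
class OrbitalMap:
    """Row index -> (atom, element, shell, m) bookkeeping for one geometry."""
    atoms: np.ndarray          # (n_orb,) atom index per orbital
    elements: np.ndarray       # (n_orb,) atomic number per orbital
    shell_labels: list         # "s"/"p" per orbital
    shell_index: np.ndarray    # (n_orb,) index into the flat shell list
    shell_atom: np.ndarray     # (n_shells,) atom index per shell
    shell_element: np.ndarray  # (n_shells,)
    shell_l: list              # (n_shells,) "s"/"p"
    n_orb: int
    n_shells: int


def build_orbital_map(geometry: Geometry) -> OrbitalMap:
    atoms, elems, labels, shell_idx = [], [], [], []
    s_atom, s_elem, s_l = [], [], []
    for ia, z in enumerate(geometry.atomic_numbers):
        z = int(z)
        for l in SHELLS[z]:
            k = len(s_atom)
            s_atom.append(ia)
            s_elem.append(z)
            s_l.append(l)
            for _ in range(SHELL_DIM[l]):
                atoms.append(ia)
                elems.append(z)
                labels.append(l)
                shell_idx.append(k)
    return OrbitalMap(atoms=np.array(atoms), elements=np.array(elems),
                      shell_labels=labels, shell_index=np.array(shell_idx),
                      shell_atom=np.array(s_atom), shell_element=np.array(s_elem),
                      shell_l=s_l, n_orb=len(atoms), n_shells=len(s_atom))


def n_valence_electrons(geometry: Geometry) -> int:
    return int(sum(VALENCE_ELECTRONS[int(z)] for z in geometry.atomic_numbers))


def sk_pair_block(channel_values: dict, direction, n_orb_a: int,
                  n_orb_b: int) -> np.ndarray:
    """Two-center s/p block in the molecular frame.

    `channel_values` holds the bond-frame integrals for the ordered pair
    (A, B): ss_sigma; sp_sigma (s on A, p on B); ps_sigma (p on A, s on B);
    pp_sigma; pp_pi.  `direction` is the unit vector from A to B.  The block
    has rows = orbitals on A, columns = orbitals on B, each ordered
    s, px, py, pz.
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    block = np.zeros((n_orb_a, n_orb_b))
    block[0, 0] = channel_values.get("ss_sigma", 0.0)
    if n_orb_b == 4:
        block[0, 1:4] = d * channel_values.get("sp_sigma", 0.0)
    if n_orb_a == 4:
        # p on A seen from B: the bond axis points the other way
        block[1:4, 0] = -d * channel_values.get("ps_sigma", 0.0)
    if n_orb_a == 4 and n_orb_b == 4:
        dd = np.outer(d, d)
        block[1:4, 1:4] = (dd * channel_values.get("pp_sigma", 0.0)
                           + (np.eye(3) - dd) * channel_values.get("pp_pi", 0.0))
    return block


@dataclass
class MatrixPair:
    H1: np.ndarray
    S: np.ndarray
    orbital_map: OrbitalMap


def assemble_matrices(geometry: Geometry, params: ParameterSet) -> MatrixPair:
    """Dense H1 and S matrices for one geometry.

    The H1 diagonal carries the on-site energies, the S diagonal is one, and
    off-diagonal atom blocks come from the channel splines through the
    Slater-Koster rotation.  Channels vanish identically at and beyond their
    cutoff, so atom pairs separated by more than 4.5 angstrom contribute
    exactly zero.  Distances more than 0.05 angstrom below a channel's lower
    knot trigger a warning (the spline's first polynomial piece is still
    extrapolated).
    """
    omap = build_orbital_map(geometry)
    n = omap.n_orb
    H1 = np.zeros((n, n))
    S = np.eye(n)
    offsets = np.concatenate([[0], np.cumsum(
        [n_orbitals(int(z)) for z in geometry.atomic_numbers])])
    for ia, z in enumerate(geometry.atomic_numbers):
        z = int(z)
        o = offsets[ia]
        for l in SHELLS[z]:
            sh = params.shell(z, l)
            for m in range(SHELL_DIM[l]):
                idx = o + (0 if l == "s" else 1 + m)
                H1[idx, idx] = sh.onsite_energy

    dm = geometry.distance_matrix()
    n_under = 0
    for ia in range(geometry.n_atoms):
        za = int(geometry.atomic_numbers[ia])
        for ib in range(ia + 1, geometry.n_atoms):
            zb = int(geometry.atomic_numbers[ib])
            r = dm[ia, ib]
            d = (geometry.coordinates[ib] - geometry.coordinates[ia]) / r
            hv = params.ordered_channel_values("H1", za, zb, r)
            sv = params.ordered_channel_values("S", za, zb, r)
            sp0 = params.channel("H1", za, zb, "ss_sigma")
            if r < sp0.r_low - EXTRAPOLATION_GUARD:
                n_under += 1
            na, nb = n_orbitals(za), n_orbitals(zb)
            hb = sk_pair_block(hv, d, na, nb)
            sb = sk_pair_block(sv, d, na, nb)
            oa, ob = offsets[ia], offsets[ib]
            H1[oa:oa + na, ob:ob + nb] = hb
            H1[ob:ob + nb, oa:oa + na] = hb.T
            S[oa:oa + na, ob:ob + nb] = sb
            S[ob:ob + nb, oa:oa + na] = sb.T
    if n_under:
        warnings.warn(f"{n_under} pair distance(s) more than "
                      f"{EXTRAPOLATION_GUARD} angstrom below the spline lower "
                      "bound; extrapolating", stacklevel=2)
    return MatrixPair(H1=H1, S=S, orbital_map=omap)
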