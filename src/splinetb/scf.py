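"""Self-consistent-charge solver.

Solves the second-order tight-binding equations for a closed-shell molecule:
the Fock matrix is H1 plus a charge-fluctuation shift built from the
shell-resolved Coulomb kernel, the generalized eigenproblem is handled by
symmetric (Loewdin) orthogonalization, Mulliken analysis yields the shell
charge fluctuations, and the loop iterates with linear mixing accelerated by
Anderson extrapolation until the fluctuations reach a fixed point.

Total energy decomposition::

    E = Tr(P H1) + 1/2 dq^T G dq + E_rep + E_ref

with P the density matrix and dq the shell charge fluctuations (Mulliken
population minus the neutral-atom shell occupancy, in electrons).  Reported
atomic charges are q_A = -(population - neutral), so positive q means
electron-deficient, matching the usual charge-target convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import NEUTRAL_OCCUPANCY
from .gamma import GammaMatrix, gamma_matrix
from .geometry import Geometry
from .slako import MatrixPair, OrbitalMap, assemble_matrices, n_valence_electrons


class NotPositiveDefiniteError(ValueError):
    pass


class DegenerateFrontierError(ValueError):
    pass


@dataclass
class SCFOptions:
    tol: float = 1e-7            # max |d dq| convergence threshold, e
    max_iter: int = 60
    mixing: float = 0.3          # linear mixing fraction of the new charges
    anderson_after: int = 3      # switch on Anderson acceleration
    anderson_depth: int = 4
    gamma_scale: float = 1.0     # 0 disables self-consistency (one shot)
    gap_tol: float = 1e-8        # reject fractional occupation


@dataclass
class SCFResult:
    delta_q: np.ndarray              # per shell, electrons in excess of neutral
    delta_q_atomic: np.ndarray       # per atom
    charges: np.ndarray              # q_A = -delta_q_atomic (e)
    density_matrix: np.ndarray
    mo_energies: np.ndarray
    electronic_energy: float         # Tr(P H1), Ha
    coulomb_energy: float            # 1/2 dq G dq, Ha
    repulsive_energy: float
    reference_energy: float
    total_energy: float
    dipole: np.ndarray               # e*angstrom
    converged: bool
    n_iterations: int
    orbital_map: OrbitalMap = field(repr=False, default=None)
    S: np.ndarray = field(repr=False, default=None)


def lowdin_orthogonalizer(S: np.ndarray, min_eig: float = 1e-10) -> np.ndarray:
    s, V = np.linalg.eigh(S)
    if s.min() <= min_eig:
        raise NotPositiveDefiniteError(
            f"overlap matrix is not positive definite (min eigenvalue {s.min():.3e})")
    return V @ np.diag(s ** -0.5) @ V.T


def neutral_occupancies(omap: OrbitalMap) -> np.ndarray:
    return np.array([NEUTRAL_OCCUPANCY[(int(z), l)]
                     for z, l in zip(omap.shell_element, omap.shell_l)])


def mulliken_populations(density_matrix, S, orbital_map: OrbitalMap) -> np.ndarray:
    """Per-shell Mulliken populations: sum over the shell's orbitals of
    diag(P S)."""
    d = np.sum(density_matrix * S, axis=1)   # diag(P S) for symmetric P, S
    pops = np.zeros(orbital_map.n_shells)
    np.add.at(pops, orbital_map.shell_index, d)
    return pops


def dipole_moment(geometry: Geometry, charges_atomic: np.ndarray) -> np.ndarray:
    """D = sum_A q_A R_A in e*angstrom, q positive = electron-deficient."""
    return np.asarray(charges_atomic) @ geometry.coordinates


def _diagonalize(H, X, nocc, gap_tol):
    Ht = X @ H @ X
    Ht = 0.5 * (Ht + Ht.T)
    eps, Ct = np.linalg.eigh(Ht)
    C = X @ Ct
    if nocc < len(eps) and eps[nocc] - eps[nocc - 1] < gap_tol:
        raise DegenerateFrontierError(
            f"degenerate frontier orbitals (gap {eps[nocc] - eps[nocc - 1]:.2e} Ha); "
            "fractional occupation is not supported")
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    return eps, C, P


def scf_solve(matrix_pair: MatrixPair, gamma: GammaMatrix, n_electrons: int,
              geometry: Geometry = None, repulsive_energy: float = 0.0,
              reference_energy: float = 0.0,
              options: SCFOptions = None) -> SCFResult:
    """Iterate the charge fluctuations to self-consistency.

    Non-convergence is flagged on the result, not raised, so callers can do
    their own exclusion bookkeeping.
    """
    opt = options or SCFOptions()
    omap = matrix_pair.orbital_map
    H1, S = matrix_pair.H1, matrix_pair.S
    if n_electrons % 2:
        raise ValueError("closed-shell solver requires an even electron count")
    nocc = n_electrons // 2
    X = lowdin_orthogonalizer(S)
    G = opt.gamma_scale * np.asarray(gamma)
    q0 = neutral_occupancies(omap)

    dq = np.zeros(omap.n_shells)
    hist_x, hist_g = [], []
    converged = False
    n_it = 0
    sh_orb_sum = None
    for it in range(1, opt.max_iter + 1):
        n_it = it
        shift = G @ dq
        sh_orb = shift[omap.shell_index]
        H = H1 + 0.5 * S * (sh_orb[:, None] + sh_orb[None, :])
        eps, C, P = _diagonalize(H, X, nocc, opt.gap_tol)
        dq_out = mulliken_populations(P, S, omap) - q0
        if opt.gamma_scale == 0.0:
            dq = dq_out
            converged = True
            break
        change = np.max(np.abs(dq_out - dq))
        if change < opt.tol:
            dq = dq_out
            converged = True
            break
        hist_x.append(dq.copy())
        hist_g.append(dq_out.copy())
        if len(hist_x) > opt.anderson_depth:
            hist_x.pop(0)
            hist_g.pop(0)
        if it >= opt.anderson_after and len(hist_x) >= 2:
            dq = _anderson_step(hist_x, hist_g, opt.mixing)
        else:
            dq = dq + opt.mixing * (dq_out - dq)

    # final consistent pass with the accepted charges
    shift = G @ dq
    sh_orb = shift[omap.shell_index]
    H = H1 + 0.5 * S * (sh_orb[:, None] + sh_orb[None, :])
    eps, C, P = _diagonalize(H, X, nocc, opt.gap_tol)

    e_elec = float(np.sum(P * H1))
    e_coul = float(0.5 * dq @ G @ dq)
    total = e_elec + e_coul + repulsive_energy + reference_energy
    dq_atom = np.zeros(int(omap.shell_atom.max()) + 1 if omap.n_shells else 0)
    np.add.at(dq_atom, omap.shell_atom, dq)
    charges = -dq_atom
    dip = (dipole_moment(geometry, charges) if geometry is not None
           else np.zeros(3))
    return SCFResult(delta_q=dq, delta_q_atomic=dq_atom, charges=charges,
                     density_matrix=P, mo_energies=eps,
                     electronic_energy=e_elec, coulomb_energy=e_coul,
                     repulsive_energy=repulsive_energy,
                     reference_energy=reference_energy, total_energy=total,
                     dipole=dip, converged=converged, n_iterations=n_it,
                     orbital_map=omap, S=S)


def _anderson_step(hist_x, hist_g, mixing):
    """Anderson (DIIS-like) extrapolation on the fixed-point residuals."""
    F = np.array([g - x for x, g in zip(hist_x, hist_g)])   # (m, n)
    m = len(F)
    # minimize ||sum_i c_i F_i||^2 with sum c = 1
    B = F @ F.T
    B = B + 1e-12 * np.trace(B) / m * np.eye(m)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = B
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[m] = 1.0
    try:
        c = np.linalg.solve(A, rhs)[:m]
    except np.linalg.LinAlgError:
        c = np.zeros(m)
        c[-1] = 1.0
    x_mix = sum(ci * x for ci, x in zip(c, hist_x))
    g_mix = sum(ci * g for ci, g in zip(c, hist_g))
    return x_mix + mixing * (g_mix - x_mix)


def solve_geometry(geometry: Geometry, params, options: SCFOptions = None,
                   include_repulsive: bool = True) -> SCFResult:
    """Convenience wrapper: assemble matrices, kernel, and repulsive/reference
    energies for one geometry, then run the SCC loop."""
    mp = assemble_matrices(geometry, params)
    gm = gamma_matrix(geometry, params, mp.orbital_map)
    e_rep = 0.0
    if include_repulsive and getattr(params, "repulsive", None):
        e_rep = repulsive_energy(geometry, params)
    e_ref = 0.0
    if getattr(params, "reference", None) is not None:
        e_ref = params.reference(geometry.element_counts())
    return scf_solve(mp, gm, n_valence_electrons(geometry), geometry=geometry,
                     repulsive_energy=e_rep, reference_energy=e_ref,
                     options=options)


def repulsive_energy(geometry: Geometry, params) -> float:
    """Sum of pair repulsive splines over all atom pairs, Ha."""
    from .params import canonical_pair
    dm = geometry.distance_matrix()
    e = 0.0
    for i in range(geometry.n_atoms):
        for j in range(i + 1, geometry.n_atoms):
            pair = canonical_pair(int(geometry.atomic_numbers[i]),
                                  int(geometry.atomic_numbers[j]))
            sp = params.repulsive.get(pair)
            if sp is not None:
                e += float(sp.eval(dm[i, j])[0])
    return e
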