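"""Repulsive-potential and reference-energy fitting.

The per-element reference energy

    E_ref = sum_Z N_Z C_Z + C_0

absorbs the constant per-atom shifts between any two quantum-chemical
methods; fitting it by least squares to energy differences and reporting the
MAE of the residuals is the method-comparison metric used throughout.

Because both the repulsive pair splines and the reference energy are linear
in their coefficients, fitting them to (target - electronic) energies with
shape constraints (R' <= 0 and R'' >= 0 on a dense grid, value and slope
exactly zero at the cutoff via the constrained basis) is a convex quadratic
program whose global optimum is found by the interior-point solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Dataset
from .params import ParameterSet, ReferenceEnergy, canonical_pair
from .qp import solve_qp


class RankDeficientError(ValueError):
    pass


def _element_design(element_counts_list, elements):
    X = np.zeros((len(element_counts_list), len(elements) + 1))
    for i, counts in enumerate(element_counts_list):
        for j, z in enumerate(elements):
            X[i, j] = counts.get(z, 0)
        X[i, -1] = 1.0
    return X


def fit_reference_energy(energies_a, energies_b, element_counts_list,
                         elements=None, allow_rank_deficient=False):
    """Least-squares fit of per-element coefficients to energies_b - energies_a.

    `element_counts_list` gives {Z: N_Z} per configuration.  Returns
    (ReferenceEnergy, residuals); the MAE of the residuals is the
    method-comparison metric.  With `allow_rank_deficient` the minimum-norm
    solution is used (residuals are a projection and remain unique even when
    the coefficients are not identified -- the evaluation path relies on
    this for small formula sets).
    """
    ea = np.asarray(energies_a, dtype=float)
    eb = np.asarray(energies_b, dtype=float)
    if ea.shape != eb.shape:
        raise ValueError("energy lists must have equal length")
    if elements is None:
        elements = sorted({z for c in element_counts_list for z in c})
    X = _element_design(element_counts_list, elements)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] and not allow_rank_deficient:
        # name the collinear columns
        labels = [f"N_{z}" for z in elements] + ["C_0"]
        _, s, Vt = np.linalg.svd(X)
        null = Vt[rank:]
        bad = [labels[j] for j in range(X.shape[1])
               if np.any(np.abs(null[:, j]) > 1e-8)]
        raise RankDeficientError(
            f"reference-energy design is rank deficient (rank {rank} of "
            f"{X.shape[1]}); collinear columns: {bad}")
    diff = eb - ea
    c, *_ = np.linalg.lstsq(X, diff, rcond=None)
    residuals = diff - X @ c
    ref = ReferenceEnergy(
        c_per_element={z: float(c[j]) for j, z in enumerate(elements)},
        c0=float(c[-1]))
    return ref, residuals


@dataclass
class RepulsiveLayout:
    """Column layout of the joint repulsive + reference design matrix."""
    pairs: list                 # canonical pairs in order
    slices: dict                # pair -> slice into the coefficient vector
    elements: list
    n_rep: int
    n_total: int

    @classmethod
    def from_params(cls, params: ParameterSet):
        pairs = sorted(params.repulsive)
        slices = {}
        off = 0
        for p in pairs:
            nf = params.repulsive[p].n_free
            slices[p] = slice(off, off + nf)
            off += nf
        elements = params.elements
        return cls(pairs=pairs, slices=slices, elements=elements,
                   n_rep=off, n_total=off + len(elements) + 1)

    def pack(self, params: ParameterSet) -> np.ndarray:
        v = np.zeros(self.n_total)
        for p in self.pairs:
            v[self.slices[p]] = params.repulsive[p].free
        for j, z in enumerate(self.elements):
            v[self.n_rep + j] = params.reference.c_per_element.get(z, 0.0)
        v[-1] = params.reference.c0
        return v

    def unpack(self, v: np.ndarray, params: ParameterSet):
        for p in self.pairs:
            params.repulsive[p].free = np.array(v[self.slices[p]])
        params.reference = ReferenceEnergy(
            c_per_element={z: float(v[self.n_rep + j])
                           for j, z in enumerate(self.elements)},
            c0=float(v[-1]))


def repulsive_design_row(geometry, params: ParameterSet,
                         layout: RepulsiveLayout) -> np.ndarray:
    """Row d with d @ coeffs = E_rep(geometry) + E_ref(geometry)."""
    row = np.zeros(layout.n_total)
    dm = geometry.distance_matrix()
    zs = geometry.atomic_numbers
    for i in range(geometry.n_atoms):
        for j in range(i + 1, geometry.n_atoms):
            pair = canonical_pair(int(zs[i]), int(zs[j]))
            if pair not in layout.slices:
                continue
            sp = params.repulsive[pair]
            row[layout.slices[pair]] += sp.design_matrix(
                np.array([dm[i, j]]), 0, free=True)[0]
    counts = geometry.element_counts()
    for j, z in enumerate(layout.elements):
        row[layout.n_rep + j] = counts.get(z, 0)
    row[-1] = 1.0
    return row


def shape_constraints(params: ParameterSet, layout: RepulsiveLayout,
                      grid_n: int = 500):
    """Linear inequalities: R'(r) <= 0 and -R''(r) <= 0 on a dense grid for
    every pair spline (boundary conditions already hold by construction)."""
    import scipy.sparse as sparse
    rows, n = [], layout.n_total
    for p in layout.pairs:
        sp = params.repulsive[p]
        r = sp.grid(grid_n)
        r = r[r < sp.r_cut]          # rows at the cutoff are identically zero
        M1 = sp.design_matrix(r, 1, free=True)
        M2 = sp.design_matrix(r, 2, free=True)
        for M in (M1, -M2):
            block = sparse.lil_matrix((M.shape[0], n))
            block[:, layout.slices[p]] = M
            rows.append(block.tocsr())
    G = sparse.vstack(rows).tocsr()
    return G, np.zeros(G.shape[0])


def fit_repulsive_and_reference(train_set: Dataset, electronic_energies,
                                targets, params: ParameterSet,
                                constraints: bool = True, grid_n: int = 500,
                                design=None, ridge: float = 1e-9,
                                tol: float = 1e-10):
    """Convex fit of all repulsive splines plus reference energy.

    Minimizes sum_i (target_i - electronic_i - E_rep,i - E_ref,i)^2 subject
    to the shape constraints; writes the optimum back into `params` and
    returns (layout, QPResult, residuals).  `design` may carry a precomputed
    design matrix (rows from `repulsive_design_row`).
    """
    y = np.asarray(targets, dtype=float) - np.asarray(electronic_energies,
                                                      dtype=float)
    layout = RepulsiveLayout.from_params(params)
    if design is None:
        design = np.vstack([repulsive_design_row(g, params, layout)
                            for g in train_set])
    P = 2.0 * design.T @ design
    q = -2.0 * design.T @ y
    if constraints:
        G, h = shape_constraints(params, layout, grid_n)
    else:
        G, h = None, None
    scale = max(np.trace(P) / layout.n_total, 1.0)
    res = solve_qp(P, q, G, h, tol=tol, ridge=ridge * scale)
    layout.unpack(res.x, params)
    residuals = y - design @ res.x
    return layout, res, residuals
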