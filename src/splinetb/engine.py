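"""Precompute caches and the batched, differentiable tight-binding engine.

Training runs thousands of epochs, so everything that does not depend on
trainable parameters -- distances, direction cosines, the sparse maps from
spline coefficients into matrix positions, orbital/shell bookkeeping,
electron counts, repulsive/reference design rows -- is computed once per
batch and frozen (which is also why batch membership is fixed for a whole
run).  Rebuilding H1 and S for new coefficients is then a single sparse
matrix-vector product per batch.

The forward pass solves the generalized eigenproblem with *frozen* charge
fluctuations (the loop-inversion scheme: full SCC solves happen only at the
periodic refresh).  The backward pass propagates loss adjoints to every
trainable parameter analytically:

* the density matrix is differentiated with occupied-subspace perturbation
  theory, which needs only occupied-virtual energy denominators and is
  therefore stable under degeneracies *within* the occupied or virtual
  blocks;
* Hubbard derivatives of the Coulomb kernel come from a complex-step
  evaluation of the analytic kernel (machine-precision, no hand-derived
  expression);
* spline-coefficient and on-site gradients are the transposed sparse
  design maps.

Configurations of different sizes are padded to a common orbital count;
padded orbitals are decoupled identity rows in S with large distinct
diagonal energies in H1, so they stay unoccupied and never mix with
physical states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse

from .elements import NEUTRAL_OCCUPANCY, SHELLS, n_orbitals
from .gamma import TAU_FACTOR, shell_parameter_index
from .params import ParameterSet, canonical_pair, resolve_channel
from .repulsive import RepulsiveLayout, repulsive_design_row
from .scf import DegenerateFrontierError, NotPositiveDefiniteError
from .slako import build_orbital_map, n_valence_electrons, sk_pair_block
from .units import ANGSTROM_TO_BOHR

#: padded orbitals get these H diagonal energies (far above any physical MO)
PAD_DIAG_BASE = 1.0e3
PAD_DIAG_STEP = 10.0

ORDERED_LABELS = ("ss_sigma", "sp_sigma", "ps_sigma", "pp_sigma", "pp_pi")


class ParamLayout:
    """Flat index layout of the gradient-trained parameters.

    Order: all H1 spline free coefficients, all S spline free coefficients,
    on-site energies, Hubbard parameters, inflection latents (S channels).
    """

    def __init__(self, params: ParameterSet):
        self.spline_slices = {}
        off = 0
        for kind, store in (("H1", params.hamiltonian), ("S", params.overlap)):
            for pair in sorted(store):
                for ch in sorted(store[pair]):
                    n = store[pair][ch].n_free
                    self.spline_slices[(kind, pair, ch)] = slice(off, off + n)
                    off += n
        self.n_spline = off
        self.onsite = {}
        for z in params.elements:
            for l in SHELLS[z]:
                self.onsite[(z, l)] = off
                off += 1
        self.hubbard_params = shell_parameter_index(params.elements)
        self.hubbard_start = off
        self.hubbard = {}
        for zl in self.hubbard_params:
            self.hubbard[zl] = off
            off += 1
        self.n_hubbard = len(self.hubbard_params)
        self.inflection = {}
        for pair in sorted(params.overlap):
            for ch in sorted(params.overlap[pair]):
                if params.overlap[pair][ch].inflection_latent is not None:
                    self.inflection[(pair, ch)] = off
                    off += 1
        self.n_params = off

    @property
    def hubbard_slice(self):
        return slice(self.hubbard_start, self.hubbard_start + self.n_hubbard)

    def pack(self, params: ParameterSet) -> np.ndarray:
        v = np.zeros(self.n_params)
        for (kind, pair, ch), sl in self.spline_slices.items():
            store = params.hamiltonian if kind == "H1" else params.overlap
            v[sl] = store[pair][ch].free
        for (z, l), i in self.onsite.items():
            v[i] = params.shell(z, l).onsite_energy
        for (z, l), i in self.hubbard.items():
            v[i] = params.shell(z, l).hubbard
        for (pair, ch), i in self.inflection.items():
            v[i] = params.overlap[pair][ch].inflection_latent
        return v

    def unpack(self, theta: np.ndarray, params: ParameterSet) -> ParameterSet:
        for (kind, pair, ch), sl in self.spline_slices.items():
            store = params.hamiltonian if kind == "H1" else params.overlap
            store[pair][ch].free = np.array(theta[sl])
        for (z, l), i in self.onsite.items():
            params.shell(z, l).onsite_energy = float(theta[i])
        for (z, l), i in self.hubbard.items():
            params.shell(z, l).hubbard = float(theta[i])
        for (pair, ch), i in self.inflection.items():
            params.overlap[pair][ch].inflection_latent = float(theta[i])
        return params


@dataclass
class BatchCache:
    """Parameter-independent quantities for a fixed list of geometries."""
    n_conf: int
    N: int                       # padded orbital count
    NS: int                      # padded shell count
    NA: int                      # padded atom count
    A_H: sparse.csr_matrix       # (n_conf*N*N, n_params) -> stacked H1
    A_S: sparse.csr_matrix
    h_const: np.ndarray          # (n_conf, N, N) padding diagonal
    s_const: np.ndarray          # (n_conf, N, N) identity
    shell_of_orb: np.ndarray     # (n_conf, N) -> [0, NS]; NS = padding slot
    T_shell: np.ndarray          # (n_conf, NS, N) one-hot aggregation
    shell_valid: np.ndarray      # (n_conf, NS) bool
    R_shell: np.ndarray          # (n_conf, NS, NS) bohr
    shell_param: np.ndarray      # (n_conf, NS) index into hubbard params
    neutral_occ: np.ndarray      # (n_conf, NS)
    occ_mask: np.ndarray         # (n_conf, N) 1.0 for occupied MO slots
    nocc: np.ndarray             # (n_conf,)
    atom_of_shell: np.ndarray    # (n_conf, NS)
    coords: np.ndarray           # (n_conf, NA, 3) angstrom, padding 0
    atom_valid: np.ndarray       # (n_conf, NA) bool
    n_heavy: np.ndarray
    n_atoms: np.ndarray
    rep_design: np.ndarray       # (n_conf, rep_layout.n_total)
    target_energy: np.ndarray    # (n_conf,) NaN when absent
    target_dipole: np.ndarray    # (n_conf, 3)
    target_charges: np.ndarray   # (n_conf, NA)
    frozen_dq: np.ndarray = None  # (n_conf, NS) mutable SCC state
    valid: np.ndarray = None      # (n_conf,) SCC bookkeeping
    A_H_T: sparse.csr_matrix = field(default=None, repr=False)
    A_S_T: sparse.csr_matrix = field(default=None, repr=False)
    T_atom: np.ndarray = field(default=None, repr=False)  # (n_conf, NA, NS)

    def __post_init__(self):
        if self.frozen_dq is None:
            self.frozen_dq = np.zeros((self.n_conf, self.NS))
        if self.valid is None:
            self.valid = np.ones(self.n_conf, dtype=bool)
        if self.A_H_T is None:
            self.A_H_T = self.A_H.T.tocsr()
            self.A_S_T = self.A_S.T.tocsr()
        if self.T_atom is None:
            self.T_atom = np.zeros((self.n_conf, self.NA, self.NS))
            b = np.repeat(np.arange(self.n_conf), self.NS)
            a = self.atom_of_shell.ravel()
            s = np.tile(np.arange(self.NS), self.n_conf)
            v = self.shell_valid.ravel()
            self.T_atom[b[v], a[v], s[v]] = 1.0

    def digest(self) -> str:
        import hashlib
        m = hashlib.sha256()
        for a in (self.A_H.data, self.A_H.indices, self.A_S.data, self.h_const,
                  self.s_const, self.R_shell, self.rep_design, self.coords):
            m.update(np.ascontiguousarray(a).tobytes())
        return m.hexdigest()


def precompute_batch(geometries, params: ParameterSet,
                     layout: ParamLayout = None,
                     rep_layout: RepulsiveLayout = None,
                     target_method: str = "toy-truth") -> BatchCache:
    """Build the cache for one (frozen) batch of geometries."""
    if layout is None:
        layout = ParamLayout(params)
    if rep_layout is None:
        rep_layout = RepulsiveLayout.from_params(params)
    B = len(geometries)
    if B == 0:
        raise ValueError("batch must be nonempty")
    omaps = [build_orbital_map(g) for g in geometries]
    N = max(m.n_orb for m in omaps)
    NS = max(m.n_shells for m in omaps)
    NA = max(g.n_atoms for g in geometries)

    h_const = np.zeros((B, N, N))
    s_const = np.zeros((B, N, N))
    shell_of_orb = np.full((B, N), NS, dtype=int)
    T_shell = np.zeros((B, NS, N))
    shell_valid = np.zeros((B, NS), dtype=bool)
    R_shell = np.ones((B, NS, NS))
    shell_param = np.zeros((B, NS), dtype=int)
    neutral = np.zeros((B, NS))
    occ_mask = np.zeros((B, N))
    nocc = np.zeros(B, dtype=int)
    atom_of_shell = np.zeros((B, NS), dtype=int)
    coords = np.zeros((B, NA, 3))
    atom_valid = np.zeros((B, NA), dtype=bool)
    n_heavy = np.zeros(B, dtype=int)
    n_atoms = np.zeros(B, dtype=int)
    rep_design = np.zeros((B, rep_layout.n_total))
    t_e = np.full(B, np.nan)
    t_d = np.full((B, 3), np.nan)
    t_c = np.full((B, NA), np.nan)

    hub_index = {zl: i for i, zl in enumerate(layout.hubbard_params)}
    rowsH, colsH, valsH = [], [], []
    rowsS, colsS, valsS = [], [], []
    pair_tasks = {}

    for b, (g, omap) in enumerate(zip(geometries, omaps)):
        no = omap.n_orb
        ns = omap.n_shells
        na = g.n_atoms
        n_atoms[b] = na
        n_heavy[b] = g.n_heavy
        coords[b, :na] = g.coordinates
        atom_valid[b, :na] = True
        s_const[b][np.diag_indices(N)] = 1.0
        for k in range(no, N):
            h_const[b, k, k] = PAD_DIAG_BASE + PAD_DIAG_STEP * k
        shell_of_orb[b, :no] = omap.shell_index
        for s in range(ns):
            T_shell[b, s, :no] = (omap.shell_index == s)
        shell_valid[b, :ns] = True
        atom_of_shell[b, :ns] = omap.shell_atom
        pos = g.coordinates[omap.shell_atom] * ANGSTROM_TO_BOHR
        R_shell[b, :ns, :ns] = np.linalg.norm(
            pos[:, None] - pos[None, :], axis=-1)
        for s in range(ns):
            z, l = int(omap.shell_element[s]), omap.shell_l[s]
            shell_param[b, s] = hub_index[(z, l)]
            neutral[b, s] = NEUTRAL_OCCUPANCY[(z, l)]
        ne = n_valence_electrons(g)
        if ne % 2:
            raise ValueError(f"geometry {b}: odd electron count {ne}")
        nocc[b] = ne // 2
        occ_mask[b, :nocc[b]] = 1.0

        tgt = g.targets.get(target_method, {})
        if tgt.get("energy") is not None:
            t_e[b] = tgt["energy"]
        if tgt.get("dipole") is not None:
            t_d[b] = tgt["dipole"]
        if tgt.get("charges") is not None:
            t_c[b, :na] = tgt["charges"]

        rep_design[b] = repulsive_design_row(g, params, rep_layout)

        # on-site energies on the H1 diagonal
        offsets = np.concatenate([[0], np.cumsum(
            [n_orbitals(int(z)) for z in g.atomic_numbers])])
        for ia, z in enumerate(g.atomic_numbers):
            z = int(z)
            o = offsets[ia]
            for l in SHELLS[z]:
                col = layout.onsite[(z, l)]
                for m in range(1 if l == "s" else 3):
                    idx = o + (0 if l == "s" else 1 + m)
                    rowsH.append(np.array([b * N * N + idx * N + idx]))
                    colsH.append(np.array([col]))
                    valsH.append(np.array([1.0]))

        # collect off-diagonal pair tasks; basis rows are evaluated in one
        # batched call per canonical pair below (all electronic channels of
        # a pair share the same knot vector)
        dm = g.distance_matrix()
        for ia in range(na):
            za = int(g.atomic_numbers[ia])
            for ib in range(ia + 1, na):
                zb = int(g.atomic_numbers[ib])
                r = dm[ia, ib]
                d = (g.coordinates[ib] - g.coordinates[ia]) / r
                cpair = canonical_pair(za, zb)
                pair_tasks.setdefault(cpair, []).append(
                    (b, r, d, offsets[ia], offsets[ib], za, zb))

    for cpair, tasks in pair_tasks.items():
        ref_spline = params.hamiltonian[cpair]["ss_sigma"]
        sig = (ref_spline.r_low, ref_spline.r_cut, ref_spline.n_knots,
               ref_spline.degree)
        for store in (params.hamiltonian, params.overlap):
            for spl in store[cpair].values():
                if (spl.r_low, spl.r_cut, spl.n_knots, spl.degree) != sig:
                    raise ValueError(
                        f"electronic channels of pair {cpair} must share one "
                        "knot basis")
        rs = np.array([t[1] for t in tasks])
        W = ref_spline.design_matrix(rs, 0, free=True)
        for (b, r, d, oa, ob, za, zb), w in zip(tasks, W):
            wnz = np.nonzero(w)[0]
            wv = w[wnz]
            K = len(wnz)
            na_o, nb_o = n_orbitals(za), n_orbitals(zb)
            for label in ORDERED_LABELS:
                stored = resolve_channel(za, zb, label)
                if stored is None:
                    continue
                gblock = sk_pair_block({label: 1.0}, d, na_o, nb_o)
                nz = np.argwhere(gblock != 0.0)
                if len(nz) == 0:
                    continue
                mu, nu = nz[:, 0], nz[:, 1]
                gv = gblock[mu, nu]
                base1 = b * N * N + (oa + mu) * N + (ob + nu)
                base2 = b * N * N + (ob + nu) * N + (oa + mu)
                for kind, rows, cols, vals in (
                        ("H1", rowsH, colsH, valsH),
                        ("S", rowsS, colsS, valsS)):
                    sl = layout.spline_slices[(kind, cpair, stored)]
                    vv = np.outer(gv, wv).ravel()
                    cc = np.tile(sl.start + wnz, len(gv))
                    rows.append(np.repeat(base1, K))
                    rows.append(np.repeat(base2, K))
                    cols.append(cc)
                    cols.append(cc)
                    vals.append(vv)
                    vals.append(vv)

    shape = (B * N * N, layout.n_params)

    def build(rows, cols, vals):
        if not rows:
            return sparse.csr_matrix(shape)
        return sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))), shape=shape)

    A_H = build(rowsH, colsH, valsH)
    A_S = build(rowsS, colsS, valsS)
    return BatchCache(n_conf=B, N=N, NS=NS, NA=NA, A_H=A_H, A_S=A_S,
                      h_const=h_const, s_const=s_const,
                      shell_of_orb=shell_of_orb, T_shell=T_shell,
                      shell_valid=shell_valid, R_shell=R_shell,
                      shell_param=shell_param, neutral_occ=neutral,
                      occ_mask=occ_mask, nocc=nocc,
                      atom_of_shell=atom_of_shell, coords=coords,
                      atom_valid=atom_valid, n_heavy=n_heavy, n_atoms=n_atoms,
                      rep_design=rep_design, target_energy=t_e,
                      target_dipole=t_d, target_charges=t_c)


def slice_cache(cache: BatchCache, a: int, b: int) -> BatchCache:
    """View of configurations [a, b) of a cache.

    Dense per-configuration arrays are numpy views, so a refresh on the
    parent cache updates the slices' frozen charges and validity flags in
    place; only the sparse design maps are row-sliced copies.
    """
    N = cache.N
    return BatchCache(
        n_conf=b - a, N=N, NS=cache.NS, NA=cache.NA,
        A_H=cache.A_H[a * N * N:b * N * N].tocsr(),
        A_S=cache.A_S[a * N * N:b * N * N].tocsr(),
        h_const=cache.h_const[a:b], s_const=cache.s_const[a:b],
        shell_of_orb=cache.shell_of_orb[a:b], T_shell=cache.T_shell[a:b],
        shell_valid=cache.shell_valid[a:b], R_shell=cache.R_shell[a:b],
        shell_param=cache.shell_param[a:b], neutral_occ=cache.neutral_occ[a:b],
        occ_mask=cache.occ_mask[a:b], nocc=cache.nocc[a:b],
        atom_of_shell=cache.atom_of_shell[a:b], coords=cache.coords[a:b],
        atom_valid=cache.atom_valid[a:b], n_heavy=cache.n_heavy[a:b],
        n_atoms=cache.n_atoms[a:b], rep_design=cache.rep_design[a:b],
        target_energy=cache.target_energy[a:b],
        target_dipole=cache.target_dipole[a:b],
        target_charges=cache.target_charges[a:b],
        frozen_dq=cache.frozen_dq[a:b], valid=cache.valid[a:b],
        T_atom=cache.T_atom[a:b])


# ---------------------------------------------------------------------------


def _gamma_masks(cache: BatchCache):
    """Geometry-fixed branch masks for the batched kernel evaluation."""
    if getattr(cache, "_gmask", None) is None:
        mask = (cache.shell_valid[:, :, None]
                & cache.shell_valid[:, None, :]).astype(float)
        zero = np.abs(cache.R_shell) < 1e-12
        equal = cache.shell_param[:, :, None] == cache.shell_param[:, None, :]
        R_safe = np.where(zero, 1.0, cache.R_shell)
        cache._gmask = (mask, zero, equal, R_safe)
    return cache._gmask


def _gamma_branchless(R_safe, zero, equal, ta, tb):
    """All three kernel branches evaluated densely, then selected.

    Safe denominators keep the unequal-decay branch finite where it is not
    selected; correctness is guaranteed by the selection masks.
    """
    tm = 0.5 * (ta + tb)
    g_eq = 1.0 / R_safe - np.exp(-tm * R_safe) * (
        1.0 / R_safe + 11.0 * tm / 16.0 + 3.0 * tm ** 2 * R_safe / 16.0
        + tm ** 3 * R_safe ** 2 / 48.0)
    da = ta ** 2 - tb ** 2
    da = np.where(equal, 1.0, da)

    def half(a, b, d):
        f = (a * b ** 4) / (2.0 * d ** 2) \
            - (b ** 6 - 3.0 * a ** 2 * b ** 4) / (d ** 3 * R_safe)
        return np.exp(-a * R_safe) * f

    g_un = 1.0 / R_safe - half(ta, tb, da) - half(tb, ta, -da)
    g_on = ta * tb * (ta ** 2 + 3.0 * ta * tb + tb ** 2) \
        / (2.0 * (ta + tb) ** 3)
    return np.where(zero, g_on, np.where(equal, g_eq, g_un))


def _batched_gamma(cache: BatchCache, U_params: np.ndarray,
                   derivatives: bool = False):
    """Shell-pair Coulomb kernel per configuration.

    With ``derivatives`` also returns the elementwise partials with respect
    to the *left* and *right* shell Hubbard (complex step; two evaluations
    regardless of how many distinct Hubbard parameters exist -- the backward
    pass scatters them onto parameters via the shell->parameter index map).
    """
    U = U_params[cache.shell_param]                       # (B, NS)
    mask, zero, equal, R_safe = _gamma_masks(cache)
    ta = TAU_FACTOR * U[:, :, None]
    tb = TAU_FACTOR * U[:, None, :]
    if not derivatives:
        return _gamma_branchless(R_safe, zero, equal, ta, tb) * mask, None, None
    h = 1e-30
    Ga = _gamma_branchless(R_safe, zero, equal, ta + 1j * h * TAU_FACTOR, tb)
    Gb = _gamma_branchless(R_safe, zero, equal, ta, tb + 1j * h * TAU_FACTOR)
    return Ga.real * mask, (Ga.imag / h) * mask, (Gb.imag / h) * mask


@dataclass
class Forward:
    """Intermediates of one frozen-charge forward pass, kept for backward."""
    theta: np.ndarray
    H1: np.ndarray
    S: np.ndarray
    G: np.ndarray
    dGa: np.ndarray              # d(gamma)/d(U of left shell), elementwise
    dGb: np.ndarray
    shift_orb: np.ndarray
    eps: np.ndarray
    C: np.ndarray
    P: np.ndarray
    pops: np.ndarray
    dq_pred: np.ndarray          # (B, NS) predicted shell fluctuations
    charges: np.ndarray          # (B, NA) predicted atomic charges
    dipole: np.ndarray           # (B, 3)
    e_elec: np.ndarray           # Tr(P H1)
    e_coul: np.ndarray           # with frozen dq
    e_rep_ref: np.ndarray
    energy: np.ndarray           # (B,) total
    ok: np.ndarray = None        # (B,) electronic-structure validity


def _gather_shift(cache: BatchCache, shift_shell):
    padded = np.concatenate(
        [shift_shell, np.zeros((cache.n_conf, 1))], axis=1)
    return np.take_along_axis(padded, cache.shell_of_orb, axis=1)


def _lowdin_batch(S: np.ndarray, strict: bool = True):
    """Batched symmetric orthogonalizer; configurations whose overlap is not
    positive definite get an identity placeholder and a False flag."""
    s, V = np.linalg.eigh(S)
    ok = s.min(axis=1) > 1e-10
    if not ok.all():
        if strict:
            raise NotPositiveDefiniteError(
                f"overlap not positive definite (min eig {s.min():.3e})")
        s = np.where(ok[:, None], s, 1.0)
    X = (V * (s ** -0.5)[:, None, :]) @ np.swapaxes(V, 1, 2)
    return X, ok


def _density(C, occ_mask):
    Co = C * occ_mask[:, None, :]
    return 2.0 * (Co @ np.swapaxes(Co, 1, 2))


def forward(cache: BatchCache, theta: np.ndarray, layout: ParamLayout,
            rep_vec: np.ndarray, need_grad: bool = True,
            dq: np.ndarray = None, gap_tol: float = 1e-8,
            strict: bool = False) -> Forward:
    """Frozen-charge forward pass for one batch.

    `rep_vec` is the packed repulsive+reference coefficient vector (held
    fixed between refreshes); `dq` overrides the cache's frozen charge
    fluctuations (used inside the SCC refresh loop).  Configurations with a
    non-positive-definite overlap or a degenerate frontier gap are flagged
    in ``Forward.ok`` (and raise only under ``strict``); their numbers are
    placeholders and must be masked by the caller.
    """
    B, N = cache.n_conf, cache.N
    H1 = (cache.A_H @ theta).reshape(B, N, N) + cache.h_const
    S = (cache.A_S @ theta).reshape(B, N, N) + cache.s_const
    U = theta[layout.hubbard_slice]
    G, dGa, dGb = _batched_gamma(cache, U, derivatives=need_grad)
    if dq is None:
        dq = cache.frozen_dq
    shift_shell = (G @ dq[:, :, None])[:, :, 0]
    shift_orb = _gather_shift(cache, shift_shell)
    H = H1 + 0.5 * S * (shift_orb[:, :, None] + shift_orb[:, None, :])

    X, ok = _lowdin_batch(S, strict=strict)
    Ht = X @ H @ X
    Ht = 0.5 * (Ht + np.swapaxes(Ht, 1, 2))
    eps, Ct = np.linalg.eigh(Ht)
    C = X @ Ct
    homo = np.take_along_axis(eps, cache.nocc[:, None] - 1, axis=1)[:, 0]
    lumo = np.take_along_axis(eps, cache.nocc[:, None], axis=1)[:, 0]
    gap_bad = lumo - homo < gap_tol
    if strict and gap_bad.any():
        raise DegenerateFrontierError(
            "degenerate frontier orbitals in configurations "
            f"{np.where(gap_bad)[0].tolist()}")
    ok = ok & ~gap_bad
    P = _density(C, cache.occ_mask)

    diag_PS = np.sum(P * S, axis=2)
    pops = (cache.T_shell @ diag_PS[:, :, None])[:, :, 0]
    dq_pred = pops - cache.neutral_occ
    charges = -(cache.T_atom @ dq_pred[:, :, None])[:, :, 0]
    dipole = np.sum(charges[:, :, None] * cache.coords, axis=1)
    e_elec = np.sum(P * H1, axis=(1, 2))
    e_coul = 0.5 * np.sum(dq * shift_shell, axis=1)
    e_rep_ref = cache.rep_design @ rep_vec
    energy = e_elec + e_coul + e_rep_ref
    return Forward(theta=theta, H1=H1, S=S, G=G, dGa=dGa, dGb=dGb,
                   shift_orb=shift_orb,
                   eps=eps, C=C, P=P, pops=pops, dq_pred=dq_pred,
                   charges=charges, dipole=dipole, e_elec=e_elec,
                   e_coul=e_coul, e_rep_ref=e_rep_ref, energy=energy, ok=ok)


def backward(cache: BatchCache, fw: Forward, layout: ParamLayout,
             e_bar: np.ndarray, dip_bar: np.ndarray,
             charge_bar: np.ndarray) -> np.ndarray:
    """Propagate adjoints of (energy, dipole, atomic charges) to theta."""
    B, N = cache.n_conf, cache.N
    dq = cache.frozen_dq
    Ct = np.swapaxes(fw.C, 1, 2)

    q_bar = np.array(charge_bar, dtype=float)
    q_bar += (cache.coords @ dip_bar[:, :, None])[:, :, 0]
    q_bar *= cache.atom_valid
    # charges = -sum of shell dq_pred on each atom
    pop_bar = -(np.swapaxes(cache.T_atom, 1, 2) @ q_bar[:, :, None])[:, :, 0]
    w_orb = _gather_shift(cache, pop_bar)          # (B, N)

    P_bar = w_orb[:, :, None] * fw.S + e_bar[:, None, None] * fw.H1
    S_bar = w_orb[:, :, None] * fw.P
    H1_bar = e_bar[:, None, None] * fw.P

    # density-matrix backward (occupied-virtual perturbation)
    Gsym = 0.5 * (P_bar + np.swapaxes(P_bar, 1, 2))
    A = Ct @ Gsym @ fw.C
    occ = cache.occ_mask
    virt = 1.0 - occ
    # denominator eps_q - eps_p with q occupied (col), p virtual (row)
    denom = fw.eps[:, None, :] - fw.eps[:, :, None]
    # flagged configurations carry zero adjoints; keep their denominators
    # finite so no NaN leaks through the masked contributions
    denom = np.where(denom >= 0, 1.0, -1.0) * np.maximum(np.abs(denom), 1e-10)
    mask = virt[:, :, None] * occ[:, None, :]
    F = np.where(mask > 0, 4.0 / np.where(mask > 0, denom, 1.0), 0.0)
    W = A * F
    H_bar = fw.C @ W @ Ct
    PG = fw.P @ Gsym
    S_bar = S_bar - fw.C @ (W * fw.eps[:, None, :]) @ Ct \
        - 0.5 * (PG @ fw.P)

    # Fock = H1 + 0.5 S (shift_mu + shift_nu)
    H1_bar = H1_bar + H_bar
    shift_sum = fw.shift_orb[:, :, None] + fw.shift_orb[:, None, :]
    S_bar = S_bar + 0.5 * H_bar * shift_sum
    Hs = 0.5 * (H_bar + np.swapaxes(H_bar, 1, 2))
    sh_orb_bar = np.sum(Hs * fw.S, axis=2)
    sh_shell_bar = (cache.T_shell @ sh_orb_bar[:, :, None])[:, :, 0]

    grad = cache.A_H_T @ H1_bar.ravel()
    grad = grad + cache.A_S_T @ S_bar.ravel()

    # Hubbard gradient: through the shift and the frozen Coulomb energy
    G_gamma_bar = sh_shell_bar[:, :, None] * dq[:, None, :]
    G_gamma_bar += 0.5 * e_bar[:, None, None] * dq[:, :, None] * dq[:, None, :]
    nh = layout.n_hubbard
    wa = np.sum(G_gamma_bar * fw.dGa, axis=2)      # (B, NS) left-shell partials
    wb = np.sum(G_gamma_bar * fw.dGb, axis=1)
    flat = cache.shell_param.ravel()
    hub_grad = (np.bincount(flat, weights=wa.ravel(), minlength=nh)
                + np.bincount(flat, weights=wb.ravel(), minlength=nh))
    grad[layout.hubbard_slice] += hub_grad
    return grad


# ---------------------------------------------------------------------------


def scc_refresh(cache: BatchCache, theta: np.ndarray, layout: ParamLayout,
                tol: float = 1e-7, max_iter: int = 60, mixing: float = 0.3,
                anderson_after: int = 3, anderson_depth: int = 4,
                dq0: np.ndarray = None):
    """Full batched SCC solve; writes the converged fluctuations into
    ``cache.frozen_dq`` (in place, so sliced views stay coherent) and flags
    non-converged configurations in ``cache.valid``.

    `dq0` warm-starts the iteration (e.g. the previous refresh's charges).
    Returns (converged mask, electronic+Coulomb energy per configuration).
    """
    B, N, NS = cache.n_conf, cache.N, cache.NS
    H1 = (cache.A_H @ theta).reshape(B, N, N) + cache.h_const
    S = (cache.A_S @ theta).reshape(B, N, N) + cache.s_const
    U = theta[layout.hubbard_slice]
    G, _, _ = _batched_gamma(cache, U, derivatives=False)
    X, spd_ok = _lowdin_batch(S, strict=False)

    dq = np.zeros((B, NS)) if dq0 is None else np.array(dq0, dtype=float)
    done = np.zeros(B, dtype=bool)
    hx, hg = [], []

    def one_shot(dq_in):
        shift_orb = _gather_shift(cache, (G @ dq_in[:, :, None])[:, :, 0])
        H = H1 + 0.5 * S * (shift_orb[:, :, None] + shift_orb[:, None, :])
        Ht = X @ H @ X
        Ht = 0.5 * (Ht + np.swapaxes(Ht, 1, 2))
        eps, Ct = np.linalg.eigh(Ht)
        C = X @ Ct
        P = _density(C, cache.occ_mask)
        pops = (cache.T_shell @ np.sum(P * S, axis=2)[:, :, None])[:, :, 0]
        return P, pops - cache.neutral_occ

    for it in range(1, max_iter + 1):
        P, dq_out = one_shot(dq)
        change = np.max(np.abs((dq_out - dq) * cache.shell_valid), axis=1)
        done = done | (change < tol)
        if done.all():
            break
        hx.append(dq.copy())
        hg.append(dq_out.copy())
        if len(hx) > anderson_depth:
            hx.pop(0)
            hg.pop(0)
        if it >= anderson_after and len(hx) >= 2:
            dq_new = _anderson_batch(hx, hg, mixing)
        else:
            dq_new = dq + mixing * (dq_out - dq)
        # converged configurations are frozen: the raw (unmixed) map may be
        # unstable and must not keep iterating them
        dq = np.where(done[:, None], dq, dq_new)

    P, _ = one_shot(dq)
    done = done & spd_ok
    cache.frozen_dq[...] = dq
    cache.valid[...] = done
    e = (np.sum(P * H1, axis=(1, 2))
         + 0.5 * np.sum(cache.frozen_dq
                        * (G @ cache.frozen_dq[:, :, None])[:, :, 0], axis=1))
    return done, e


def _anderson_batch(hx, hg, mixing):
    Xs = np.stack(hx, axis=1)          # (B, m, NS)
    Gs = np.stack(hg, axis=1)
    F = Gs - Xs
    m = F.shape[1]
    B = F.shape[0]
    BB = np.einsum("bmn,bkn->bmk", F, F)
    BB += 1e-12 * np.trace(BB, axis1=1, axis2=2)[:, None, None] * \
        np.eye(m)[None] / m
    A = np.zeros((B, m + 1, m + 1))
    A[:, :m, :m] = BB
    A[:, :m, m] = 1.0
    A[:, m, :m] = 1.0
    rhs = np.zeros((B, m + 1))
    rhs[:, m] = 1.0
    try:
        c = np.linalg.solve(A, rhs[:, :, None])[:, :m, 0]
    except np.linalg.LinAlgError:
        c = np.zeros((B, m))
        c[:, -1] = 1.0
    x_mix = np.einsum("bm,bmn->bn", c, Xs)
    g_mix = np.einsum("bm,bmn->bn", c, Gs)
    return x_mix + mixing * (g_mix - x_mix)
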