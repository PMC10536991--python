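"""Slater-Koster file export/import (classic, non-extended dialect).

One file per ordered element pair ``A-B.skf``.  The header carries the
radial grid (0.02 bohr spacing); homonuclear files additionally carry the
on-site energies, Hubbard parameters and neutral occupancies.  The H/S
integral table has the canonical 20 columns (d channels are written as
zeros for this s/p-basis model):

    Hdd0 Hdd1 Hdd2 Hpd0 Hpd1 Hpp0 Hpp1 Hsd0 Hsp0 Hss0  Sdd0 ... Sss0

with ``Hsp0`` the sigma integral of the s orbital on A with the p orbital
on B.  The repulsive potential is written as the standard cubic-spline
block with an exponential short-range head.  All values in the file are in
atomic units (hartree / bohr); the in-memory API converts to the package's
angstrom convention.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, CubicSpline, PPoly

from .elements import NEUTRAL_OCCUPANCY, SHELLS, atomic_number, symbol
from .params import (MissingChannelError, ParameterSet, ReferenceEnergy,
                     Shell, canonical_pair, pair_channels, resolve_channel)
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

GRID_DIST_BOHR = 0.02
MASSES = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999}

#: table column -> (kind offset handled separately) channel label, or None
TABLE_CHANNELS = ["dd_sigma", "dd_pi", "dd_delta", "pd_sigma", "pd_pi",
                  "pp_sigma", "pp_pi", "sd_sigma", "sp_sigma", "ss_sigma"]


class SkfFormatError(ValueError):
    pass


def _fmt(values):
    return "  ".join(f"{v: .12e}" for v in values)


def _ordered_channel_splines(params, kind, za, zb):
    """Spline per ordered-pair channel label (None when absent)."""
    out = {}
    for label in ("ss_sigma", "sp_sigma", "ps_sigma", "pp_sigma", "pp_pi"):
        stored = resolve_channel(za, zb, label)
        if stored is None:
            out[label] = None
        else:
            out[label] = params.channel(kind, za, zb, stored)
    return out


def skf_write(params: ParameterSet, directory, grid_dist: float = GRID_DIST_BOHR,
              r_max_angstrom: float = None) -> list:
    """Write one classic SKF file per ordered element pair.

    Electronic channels are resampled from the splines onto the uniform bohr
    grid; the repulsive spline is emitted as the cubic-spline block.
    Returns the list of paths written.
    """
    os.makedirs(directory, exist_ok=True)
    elements = params.elements
    params.validate_for(elements)
    paths = []
    for za in elements:
        for zb in elements:
            path = os.path.join(directory,
                                f"{symbol(za)}-{symbol(zb)}.skf")
            _write_pair(params, za, zb, path, grid_dist, r_max_angstrom)
            paths.append(path)
    return paths


def _write_pair(params, za, zb, path, grid_dist, r_max_angstrom):
    r_cut = max(s.r_cut for s in params.hamiltonian[canonical_pair(za, zb)]
                .values())
    if r_max_angstrom is not None:
        r_cut = max(r_cut, r_max_angstrom)
    n_grid = int(np.ceil(r_cut * ANGSTROM_TO_BOHR / grid_dist)) + 1
    r_bohr = grid_dist * np.arange(1, n_grid + 1)
    r_ang = r_bohr * BOHR_TO_ANGSTROM

    hs = _ordered_channel_splines(params, "H1", za, zb)
    ss = _ordered_channel_splines(params, "S", za, zb)

    def col(splines, name):
        spl = splines.get(name)
        return spl.eval(r_ang) if spl is not None else np.zeros(n_grid)

    table = np.zeros((n_grid, 20))
    for j, name in enumerate(TABLE_CHANNELS):
        if name == "pd_sigma" or name.startswith(("dd", "sd")):
            continue
        # pd columns are p-on-A with d-on-B: absent in an s/p basis
        table[:, j] = col(hs, name)
        table[:, 10 + j] = col(ss, name)
    # ps integrals live in the transposed file's sp column; nothing extra here

    lines = [f"{grid_dist:.6f} {n_grid}"]
    if za == zb:
        sh = params.shells[za]
        e_p = sh["p"].onsite_energy if "p" in sh else 0.0
        u_p = sh["p"].hubbard if "p" in sh else 0.0
        f_p = NEUTRAL_OCCUPANCY.get((za, "p"), 0.0)
        e_s, u_s = sh["s"].onsite_energy, sh["s"].hubbard
        f_s = NEUTRAL_OCCUPANCY[(za, "s")]
        lines.append(_fmt([0.0, e_p, e_s, 0.0, 0.0, u_p, u_s,
                           0.0, f_p, f_s]))
    mass_line = [MASSES[za]] + [0.0] * 19
    lines.append(_fmt(mass_line))
    for row in table:
        lines.append(_fmt(row))
    lines.extend(_repulsive_block(params, za, zb))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _repulsive_block(params, za, zb):
    pair = canonical_pair(za, zb)
    spl = params.repulsive.get(pair)
    if spl is None:
        raise MissingChannelError(f"missing repulsive spline for pair "
                                  f"{symbol(pair[0])}-{symbol(pair[1])}")
    bsp = BSpline(spl.knots, spl.coef, spl.degree, extrapolate=False)
    pp = PPoly.from_spline(bsp)
    # drop zero-width intervals coming from the clamped (repeated) end knots
    widths = np.diff(pp.x)
    good = np.nonzero(widths > 1e-14)[0]
    x_break = np.concatenate([pp.x[good], [pp.x[good[-1] + 1]]])
    coefs = pp.c[:, good]                # highest power first, angstrom-local
    kappa = ANGSTROM_TO_BOHR
    xs = x_break * kappa
    n_seg = len(good)
    # exponential head continuous in value and slope at the first knot
    v0 = float(spl.eval(np.array([spl.r_low]))[0])
    d0 = float(spl.eval(np.array([spl.r_low]), 1)[0]) / kappa   # Ha/bohr
    if v0 > 1e-12 and d0 < 0:
        a1 = -d0 / v0
        a2 = np.log(v0) + a1 * xs[0]
        a3 = 0.0
    else:
        a1, a2, a3 = 1.0, -30.0, 0.0
    lines = ["Spline", f"{n_seg} {xs[-1]:.12f}",
             _fmt([a1, a2, a3])]
    for k in range(n_seg):
        # ascending coefficients in bohr-local coordinates
        c_desc = coefs[:, k]                     # highest power first, in A
        deg = len(c_desc) - 1
        c_asc = [c_desc[deg - m] / kappa ** m for m in range(deg + 1)]
        row = [xs[k], xs[k + 1]] + list(c_asc)
        if k == n_seg - 1:
            row += [0.0, 0.0]                    # c4, c5 of the quintic tail
        lines.append(_fmt(row))
    return lines


# ---------------------------------------------------------------------------


@dataclass
class SkfTable:
    """Raw tabulated integrals of one ordered pair file."""
    grid_dist: float             # bohr
    n_grid: int
    H: dict                      # channel label -> (n_grid,) values, Ha
    S: dict
    repulsive_ppoly: PPoly       # in bohr
    rep_exp: tuple               # (a1, a2, a3)
    rep_cutoff: float            # bohr
    onsite: dict = None          # homonuclear only: {l: (E, U, f)}

    def r_angstrom(self):
        return (self.grid_dist * np.arange(1, self.n_grid + 1)
                * BOHR_TO_ANGSTROM)


class _TabChannel:
    """Cubic interpolation of one tabulated channel, zero beyond the table."""

    def __init__(self, r_ang, values, r_low):
        self._cs = CubicSpline(r_ang, values, extrapolate=True)
        self.r_low = r_low
        self.r_cut = r_ang[-1]

    def eval(self, r, deriv: int = 0):
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = self._cs(r, nu=deriv)
        out[r >= self.r_cut] = 0.0
        return out


class _TabRepulsive:
    def __init__(self, ppoly, exp_coefs, cutoff_bohr):
        self._pp = ppoly
        self._exp = exp_coefs
        self._cut = cutoff_bohr
        self.r_cut = cutoff_bohr * BOHR_TO_ANGSTROM

    def eval(self, r, deriv: int = 0):
        r = np.atleast_1d(np.asarray(r, dtype=float)) * ANGSTROM_TO_BOHR
        out = np.zeros_like(r)
        a1, a2, a3 = self._exp
        lo = r < self._pp.x[0]
        hi = r >= self._cut
        mid = ~lo & ~hi
        if deriv == 0:
            out[lo] = np.exp(-a1 * r[lo] + a2) + a3
            out[mid] = self._pp(r[mid])
        else:
            raise NotImplementedError("tabulated repulsive derivative")
        return out


class SkfParameterSet:
    """Tabulated parameter set read from SKF files.

    Provides the same evaluation surface that matrix assembly and the SCC
    solver use on a trainable ParameterSet, so matrices can be built from
    either representation interchangeably.
    """

    def __init__(self):
        self.shells = {}
        self.tables = {}             # ordered (za, zb) -> SkfTable
        self.repulsive = _RepView(self)
        self.reference = ReferenceEnergy()

    @property
    def elements(self):
        return sorted(self.shells)

    def shell(self, z, l):
        return self.shells[z][l]

    def channel(self, kind, za, zb, stored_label):
        # canonical stored label -> ordered file lookup
        za, zb = canonical_pair(za, zb)
        if stored_label == "ps_sigma":
            tab = self.tables[(zb, za)]
            label = "sp_sigma"
        else:
            tab = self.tables[(za, zb)]
            label = stored_label
        vals = (tab.H if kind == "H1" else tab.S)[label]
        return _TabChannel(tab.r_angstrom(), vals,
                           r_low=tab.grid_dist * BOHR_TO_ANGSTROM)

    def ordered_channel_values(self, kind, za, zb, r):
        out = {}
        tab = self.tables[(za, zb)]
        store = tab.H if kind == "H1" else tab.S
        r_ang = tab.r_angstrom()
        for label in ("ss_sigma", "sp_sigma", "pp_sigma", "pp_pi"):
            if resolve_channel(za, zb, label) is None:
                continue
            out[label] = float(_TabChannel(
                r_ang, store[label], r_ang[0]).eval(r)[0])
        if resolve_channel(za, zb, "ps_sigma") is not None:
            tab_r = self.tables[(zb, za)]
            out["ps_sigma"] = float(_TabChannel(
                tab_r.r_angstrom(), (tab_r.H if kind == "H1"
                                     else tab_r.S)["sp_sigma"],
                r_ang[0]).eval(r)[0])
        return out


class _RepView:
    def __init__(self, owner):
        self._o = owner

    def get(self, pair, default=None):
        tab = self._o.tables.get(tuple(pair))
        if tab is None:
            return default
        return _TabRepulsive(tab.repulsive_ppoly, tab.rep_exp, tab.rep_cutoff)

    def __bool__(self):
        return bool(self._o.tables)


def skf_read(directory, elements) -> SkfParameterSet:
    """Read the SKF files for every ordered pair of `elements`."""
    ps = SkfParameterSet()
    elements = sorted(atomic_number(e) if isinstance(e, str) else int(e)
                      for e in elements)
    for za in elements:
        for zb in elements:
            path = os.path.join(directory,
                                f"{symbol(za)}-{symbol(zb)}.skf")
            if not os.path.exists(path):
                raise SkfFormatError(
                    f"missing SKF file for pair {symbol(za)}-{symbol(zb)}: "
                    f"{path}")
            tab = _read_pair(path, za == zb)
            ps.tables[(za, zb)] = tab
            if za == zb:
                if tab.onsite is None:
                    raise SkfFormatError(
                        f"{path}: homonuclear file must supply on-site "
                        "energies")
                ps.shells[za] = {}
                for l in SHELLS[za]:
                    e, u, f = tab.onsite[l]
                    ps.shells[za][l] = Shell(za, l, e, u)
    # consistent grids
    gd = {p: t.grid_dist for p, t in ps.tables.items()}
    if len(set(round(v, 10) for v in gd.values())) > 1:
        raise SkfFormatError(f"inconsistent grid spacing across files: {gd}")
    return ps


def _read_pair(path, homonuclear: bool) -> SkfTable:
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    toks = raw[0].replace(",", " ").split()
    grid_dist = float(toks[0])
    n_grid = int(float(toks[1]))
    i = 1
    onsite = None
    if homonuclear:
        vals = [float(x) for x in raw[i].split()]
        if len(vals) != 10:
            raise SkfFormatError(
                f"{path}: expected a 10-entry on-site line, got "
                f"{len(vals)} entries")
        _, e_p, e_s, _, _, u_p, u_s, _, f_p, f_s = vals
        onsite = {"s": (e_s, u_s, f_s)}
        if f_p > 0 or e_p != 0.0:
            onsite["p"] = (e_p, u_p, f_p)
        i += 1
    else:
        probe = [float(x) for x in raw[i].split()]
        if len(probe) == 10:
            raise SkfFormatError(
                f"{path}: heteronuclear file must not carry an on-site line")
    i += 1                      # mass line
    table = np.array([[float(x) for x in raw[i + k].split()]
                      for k in range(n_grid)])
    if table.shape != (n_grid, 20):
        raise SkfFormatError(f"{path}: truncated or malformed H/S table "
                             f"(shape {table.shape}, expected ({n_grid}, 20))")
    i += n_grid
    H = {name: table[:, j] for j, name in enumerate(TABLE_CHANNELS)}
    S = {name: table[:, 10 + j] for j, name in enumerate(TABLE_CHANNELS)}

    while i < len(raw) and raw[i].strip() != "Spline":
        i += 1
    if i >= len(raw):
        raise SkfFormatError(f"{path}: missing repulsive Spline block")
    n_seg, cutoff = raw[i + 1].split()
    n_seg, cutoff = int(n_seg), float(cutoff)
    a1, a2, a3 = [float(x) for x in raw[i + 2].split()]
    xs, cs = [], []
    for k in range(n_seg):
        vals = [float(x) for x in raw[i + 3 + k].split()]
        x0, x1 = vals[0], vals[1]
        coefs = vals[2:]
        xs.append(x0)
        cs.append(coefs[:4])     # cubic part; quintic tail terms are zero
        if k == n_seg - 1:
            xs.append(x1)
    c = np.zeros((4, n_seg))
    for k, coefs in enumerate(cs):
        for m, cm in enumerate(coefs):
            c[3 - m, k] = cm
    pp = PPoly(c, np.array(xs))
    return SkfTable(grid_dist=grid_dist, n_grid=n_grid, H=H, S=S,
                    repulsive_ppoly=pp, rep_exp=(a1, a2, a3),
                    rep_cutoff=cutoff, onsite=onsite)
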