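"""Shell-resolved SCC Coulomb kernel.

The second-order charge-fluctuation energy uses the analytic kernel for two
interacting exponentially decaying s-like charge clouds whose decay constant
is tied to the shell Hubbard parameter by tau = (16/5) U (atomic units).
The kernel interpolates between the on-site limit gamma(0) = U (same shell)
and the bare Coulomb tail 1/R at large separation.

All formulas are evaluated with numpy ufuncs only, so a complex-step
perturbation of a Hubbard parameter propagates through and yields machine
precision derivatives d(gamma)/dU without a hand-derived expression.
"""

from __future__ import annotations

import numpy as np

from .elements import SHELLS
from .geometry import Geometry
from .slako import OrbitalMap, build_orbital_map
from .units import ANGSTROM_TO_BOHR

TAU_FACTOR = 16.0 / 5.0
_EQ_TOL = 1e-9


def _short_range_equal(tau, R):
    return np.exp(-tau * R) * (1.0 / R + 11.0 * tau / 16.0
                               + 3.0 * tau ** 2 * R / 16.0
                               + tau ** 3 * R ** 2 / 48.0)


def _short_range_unequal(ta, tb, R):
    def half(a, b):
        da = (a ** 2 - b ** 2)
        f = (a * b ** 4) / (2.0 * da ** 2) - (b ** 6 - 3.0 * a ** 2 * b ** 4) / (da ** 3 * R)
        return np.exp(-a * R) * f
    return half(ta, tb) + half(tb, ta)


def _onsite(ta, tb):
    # R -> 0 limit; reduces to 5 tau/16 = U for ta == tb
    return ta * tb * (ta ** 2 + 3.0 * ta * tb + tb ** 2) / (2.0 * (ta + tb) ** 3)


def gamma_kernel(R, Ua, Ub):
    """Kernel value(s) for separation R (bohr) and shell Hubbards (Ha).

    Accepts arrays (broadcast) and complex dtypes for derivative evaluation.
    """
    R = np.asarray(R)
    ta = TAU_FACTOR * np.asarray(Ua)
    tb = TAU_FACTOR * np.asarray(Ub)
    R, ta, tb = np.broadcast_arrays(R, ta, tb)
    out = np.zeros(R.shape, dtype=np.result_type(R, ta, tb))
    zero = np.abs(R) < 1e-12
    equal = np.abs(ta - tb) < _EQ_TOL * np.maximum(np.abs(ta), np.abs(tb))

    if np.any(zero):
        out[zero] = _onsite(ta[zero], tb[zero])
    m = zero.copy()
    sel = (~m) & equal
    if np.any(sel):
        tm = 0.5 * (ta[sel] + tb[sel])
        out[sel] = 1.0 / R[sel] - _short_range_equal(tm, R[sel])
    sel = (~m) & (~equal)
    if np.any(sel):
        out[sel] = 1.0 / R[sel] - _short_range_unequal(ta[sel], tb[sel], R[sel])
    return out


class GammaMatrix:
    """Shell-by-shell Coulomb kernel for one geometry (hartree)."""

    def __init__(self, matrix: np.ndarray, orbital_map: OrbitalMap):
        self.matrix = matrix
        self.orbital_map = orbital_map

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)


def _shell_hubbards(params, omap: OrbitalMap, override=None):
    if override is not None:
        return override
    return np.array([params.shell(int(z), l).hubbard
                     for z, l in zip(omap.shell_element, omap.shell_l)])


def gamma_matrix(geometry: Geometry, params, orbital_map: OrbitalMap = None,
                 hubbards=None) -> GammaMatrix:
    """Build the shell-resolved kernel matrix.

    `hubbards` optionally overrides the per-shell Hubbard values (used for
    complex-step differentiation); otherwise they come from `params`.
    """
    omap = orbital_map if orbital_map is not None else build_orbital_map(geometry)
    U = _shell_hubbards(params, omap, hubbards)
    coords = geometry.coordinates * ANGSTROM_TO_BOHR
    pos = coords[omap.shell_atom]
    R = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    G = gamma_kernel(R, U[:, None], U[None, :])
    return GammaMatrix(G, omap)


def shell_parameter_index(elements) -> list:
    """Flat ordering of the distinct (element, shell) Hubbard parameters."""
    out = []
    for z in sorted(elements):
        for l in SHELLS[z]:
            out.append((z, l))
    return out


def gamma_and_hubbard_derivatives(geometry: Geometry, params,
                                  orbital_map: OrbitalMap = None):
    """Kernel matrix plus dG/dU for every distinct (element, shell) Hubbard.

    Derivatives are obtained by complex step (h = 1e-30), exact to machine
    precision for this analytic kernel.
    """
    omap = orbital_map if orbital_map is not None else build_orbital_map(geometry)
    U = _shell_hubbards(params, omap)
    gm = gamma_matrix(geometry, params, omap, hubbards=U)
    pidx = shell_parameter_index(set(int(z) for z in geometry.atomic_numbers))
    h = 1e-30
    derivs = {}
    for (z, l) in pidx:
        mask = np.array([ze == z and le == l
                         for ze, le in zip(omap.shell_element, omap.shell_l)])
        if not mask.any():
            continue
        Uc = U.astype(complex)
        Uc[mask] += 1j * h
        Gc = gamma_matrix(geometry, params, omap, hubbards=Uc)
        derivs[(z, l)] = Gc.matrix.imag / h
    return gm, derivs
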