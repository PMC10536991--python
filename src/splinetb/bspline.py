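"""Constrained B-spline channels.

Every trainable distance-dependent function -- a Slater-Koster electronic
channel (H1 or S) or a repulsive pair potential (R) -- is a B-spline on a
uniform breakpoint grid over [r_low, r_cut].  Electronic channels are
quintic (continuous third derivative, which the smoothing penalty needs);
repulsive channels are cubic.

The physical boundary condition f(r_cut) = f'(r_cut) = 0 is imposed by
construction: the trainable vector lives in the null space of the two
constraint rows, so every coefficient vector reachable by training satisfies
the boundary exactly and all penalties and fits remain linear in the free
parameters.  Below r_low the first polynomial piece is continued
(no lower boundary condition); at and beyond r_cut the channel is
identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

ELECTRONIC_DEGREE = 5
REPULSIVE_DEGREE = 3


def clamped_knots(r_low: float, r_cut: float, n_breakpoints: int, degree: int):
    """Clamped uniform knot vector; n_coef = n_breakpoints + degree - 1."""
    bp = np.linspace(r_low, r_cut, n_breakpoints)
    return np.concatenate([np.full(degree, r_low), bp, np.full(degree, r_cut)])


def raw_design_matrix(t: np.ndarray, degree: int, r, deriv: int = 0) -> np.ndarray:
    """Dense matrix M with M @ c = d^deriv/dr^deriv of the spline at r.

    Extrapolates the edge polynomial pieces on both sides; cutoff masking is
    applied by the caller.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n_coef = len(t) - degree - 1
    M = np.empty((len(r), n_coef))
    for k in range(n_coef):
        c = np.zeros(n_coef)
        c[k] = 1.0
        sp = BSpline(t, c, degree, extrapolate=True)
        if deriv:
            sp = sp.derivative(deriv)
        M[:, k] = sp(r)
    return M


@dataclass
class ChannelSpline:
    """One distance-dependent channel with built-in upper boundary conditions.

    Parameters live in `free`; the full B-spline coefficients are
    ``coef = nullspace @ free``.  `kind` is "H1", "S" or "R"; `channel` is a
    Slater-Koster label ("ss_sigma", "sp_sigma", "pp_sigma", "pp_pi") or "rep".
    """

    kind: str
    pair: tuple
    channel: str
    r_low: float
    r_cut: float
    n_knots: int
    degree: int
    free: np.ndarray = None
    inflection_latent: float | None = None   # S channels: latent for inflection location
    _nullspace: np.ndarray = field(default=None, repr=False)
    _knots: np.ndarray = field(default=None, repr=False)
    _design_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.kind not in ("H1", "S", "R"):
            raise ValueError(f"unknown spline kind {self.kind!r}")
        if self.r_cut <= self.r_low:
            raise ValueError("r_cut must exceed r_low")
        self._knots = clamped_knots(self.r_low, self.r_cut, self.n_knots, self.degree)
        C = raw_design_matrix(self._knots, self.degree,
                              np.array([self.r_cut, self.r_cut]), 0)
        C[1] = raw_design_matrix(self._knots, self.degree,
                                 np.array([self.r_cut]), 1)[0]
        n_coef = C.shape[1]
        # With a clamped knot vector the value/slope at r_cut involve only the
        # last two B-spline coefficients, so the constrained subspace is simply
        # "last two coefficients zero".  Use that structured basis (it keeps
        # the per-distance design rows sparse); fall back to a generic null
        # space if the support check ever fails.
        if np.allclose(C[:, :n_coef - 2], 0.0) and \
                abs(np.linalg.det(C[:, n_coef - 2:])) > 1e-12:
            self._nullspace = np.eye(n_coef, n_coef - 2)
        else:
            self._nullspace = null_space(C)
        if self.free is None:
            self.free = np.zeros(self.n_free)
        else:
            self.free = np.asarray(self.free, dtype=float)
            if self.free.shape != (self.n_free,):
                raise ValueError(
                    f"free vector must have shape ({self.n_free},)")

    @property
    def n_coef(self) -> int:
        return len(self._knots) - self.degree - 1

    @property
    def n_free(self) -> int:
        return self._nullspace.shape[1]

    @property
    def coef(self) -> np.ndarray:
        return self._nullspace @ self.free

    @property
    def knots(self) -> np.ndarray:
        return self._knots

    @property
    def nullspace(self) -> np.ndarray:
        return self._nullspace

    def max_deriv(self) -> int:
        # simple interior knots -> C^(degree-1)
        return self.degree - 1

    def design_matrix(self, r, deriv: int = 0, free: bool = True) -> np.ndarray:
        """Matrix mapping (free or full) coefficients to derivative values at r.

        Rows for r >= r_cut are exactly zero (the channel vanishes there).
        """
        if deriv > self.max_deriv():
            raise ValueError(
                f"derivative {deriv} exceeds the smoothness class of a "
                f"degree-{self.degree} spline (max {self.max_deriv()})")
        r = np.atleast_1d(np.asarray(r, dtype=float))
        below = r < self.r_low
        inside = ~below & (r < self.r_cut)
        if deriv == 0:
            # fast path: vectorized basis evaluation inside the knot range,
            # exact zeros at/beyond the cutoff, slow extrapolation only for
            # the rare points below the lower knot
            M = np.zeros((len(r), self.n_coef))
            if inside.any():
                M[inside] = BSpline.design_matrix(
                    r[inside], self._knots, self.degree).toarray()
            if below.any():
                M[below] = raw_design_matrix(self._knots, self.degree,
                                             r[below], 0)
        else:
            M = raw_design_matrix(self._knots, self.degree, r, deriv)
            M[r >= self.r_cut] = 0.0
        return M @ self._nullspace if free else M

    def cached_design(self, key: str, r, deriv: int, free: bool = True) -> np.ndarray:
        full_key = (key, deriv, free)
        if full_key not in self._design_cache:
            self._design_cache[full_key] = self.design_matrix(r, deriv, free)
        return self._design_cache[full_key]

    def __call__(self, r, deriv: int = 0) -> np.ndarray:
        if deriv > self.max_deriv():
            raise ValueError(
                f"derivative {deriv} exceeds the smoothness class of a "
                f"degree-{self.degree} spline (max {self.max_deriv()})")
        r = np.atleast_1d(np.asarray(r, dtype=float))
        spl = BSpline(self._knots, self.coef, self.degree, extrapolate=True)
        if deriv:
            spl = spl.derivative(deriv)
        out = spl(r)
        out[r >= self.r_cut] = 0.0
        return out

    def eval(self, r, deriv: int = 0) -> np.ndarray:
        return self(r, deriv)

    def fit_values(self, r, values):
        """Least-squares fit of the free coefficients to target values."""
        A = self.design_matrix(r, 0, free=True)
        self.free, *_ = np.linalg.lstsq(A, np.asarray(values, float), rcond=None)
        return self

    def grid(self, n: int) -> np.ndarray:
        return np.linspace(self.r_low, self.r_cut, n)

    def copy(self) -> "ChannelSpline":
        return ChannelSpline(kind=self.kind, pair=self.pair, channel=self.channel,
                             r_low=self.r_low, r_cut=self.r_cut,
                             n_knots=self.n_knots, degree=self.degree,
                             free=self.free.copy(),
                             inflection_latent=self.inflection_latent)


def spline_eval(spline: ChannelSpline, r, deriv: int = 0) -> np.ndarray:
    """Functional alias for ChannelSpline evaluation."""
    return spline.eval(r, deriv)


def spline_design_matrix(spline: ChannelSpline, r_grid, deriv: int = 0,
                         free: bool = True) -> np.ndarray:
    """Functional alias for ChannelSpline.design_matrix."""
    return spline.design_matrix(r_grid, deriv, free=free)


def make_electronic_spline(kind, pair, channel, r_low, r_cut=4.5,
                           n_knots=100) -> ChannelSpline:
    return ChannelSpline(kind=kind, pair=pair, channel=channel, r_low=r_low,
                         r_cut=r_cut, n_knots=n_knots, degree=ELECTRONIC_DEGREE)


def make_repulsive_spline(pair, r_low, r_cut, n_knots=50) -> ChannelSpline:
    return ChannelSpline(kind="R", pair=pair, channel="rep", r_low=r_low,
                         r_cut=r_cut, n_knots=n_knots, degree=REPULSIVE_DEGREE)
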