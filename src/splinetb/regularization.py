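"""Shape regularization of the channel splines.

Three penalties keep the trained one-dimensional functions physically
shaped:

* a *convex* penalty: the second derivative, evaluated on a dense grid
  (500 points by default), must have a prescribed sign -- upward curvature
  for channels that approach zero from above, downward for channels
  approaching from below; violations are penalized by the squared hinge of
  the wrong-signed second derivative;
* its *single-inflection* extension for overlap channels: the required
  curvature sign flips once at a trainable inflection location, which is
  parameterized by an unconstrained latent variable squashed into
  (r_low, r_cut) and enters the penalty through a smooth sign profile so
  the location stays differentiable;
* a *smoothing* penalty: the plain sum of squared third derivatives on the
  same grid, which suppresses the piecewise-linear artifacts the convex
  penalty alone leaves behind.  It requires a continuous third derivative
  and therefore applies only to the quintic electronic channels, never to
  the cubic repulsive splines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bspline import ChannelSpline


@dataclass
class PenaltyConfig:
    grid_n: int = 500
    convex_weight: float = 1e3
    smoothing_weight: float = 1e-4
    allow_inflection: bool = True        # S channels get the inflection form
    #: width of the smooth sign flip around the inflection, in grid spacings
    inflection_softness: float = 2.0


def curvature_sign_class(spline: ChannelSpline) -> float:
    """+1 if the channel approaches zero from above (upward curvature
    required), -1 from below; decided from the channel's own values over the
    outer part of its range."""
    r = np.linspace(spline.r_low + 0.5 * (spline.r_cut - spline.r_low),
                    spline.r_cut - 1e-9, 25)
    v = spline.eval(r)
    s = np.sum(v)
    if s == 0.0:
        return 1.0
    return 1.0 if s > 0 else -1.0


def _second_derivative(spline: ChannelSpline, n_grid: int):
    r = spline.grid(n_grid)
    M2 = spline.cached_design("penalty", r, 2, free=True)
    return r, M2, M2 @ spline.free


def convex_penalty(spline: ChannelSpline, config: PenaltyConfig = None,
                   sign: float = None, with_grad: bool = False):
    """Squared-hinge penalty on wrong-signed second derivative values."""
    cfg = config or PenaltyConfig()
    if spline.degree < 2:
        raise ValueError("convex penalty needs spline order >= 3")
    s = curvature_sign_class(spline) if sign is None else float(sign)
    _, M2, f2 = _second_derivative(spline, cfg.grid_n)
    viol = np.maximum(0.0, -s * f2)
    val = float(np.sum(viol ** 2))
    if not with_grad:
        return val
    grad = M2.T @ (2.0 * viol * (-s))
    return val, grad


def inflection_location(spline: ChannelSpline) -> float:
    """Map the unconstrained latent to a location in (r_low, r_cut)."""
    lat = spline.inflection_latent
    if lat is None:
        return spline.r_low
    span = spline.r_cut - spline.r_low
    return spline.r_low + span / (1.0 + np.exp(-lat))


def latent_for_location(spline: ChannelSpline, x: float) -> float:
    span = spline.r_cut - spline.r_low
    t = np.clip((x - spline.r_low) / span, 1e-9, 1 - 1e-9)
    return float(np.log(t / (1.0 - t)))


def inflection_convex_penalty(spline: ChannelSpline,
                              config: PenaltyConfig = None,
                              sign: float = None, inflection_x: float = None,
                              with_grad: bool = False):
    """Convex penalty whose required sign flips once at the inflection point.

    `sign` is the curvature class required on the outer (large-r) side.  When
    the inflection sits at r_low the penalty reduces to the plain convex
    penalty.  Returns optionally (value, grad_free, grad_latent).
    """
    cfg = config or PenaltyConfig()
    if spline.degree < 2:
        raise ValueError("convex penalty needs spline order >= 3")
    s = curvature_sign_class(spline) if sign is None else float(sign)
    r, M2, f2 = _second_derivative(spline, cfg.grid_n)
    x = inflection_location(spline) if inflection_x is None else float(inflection_x)
    h = cfg.inflection_softness * (r[1] - r[0])
    if x <= spline.r_low + 0.5 * (r[1] - r[0]):
        # degenerate placement: reduces to the plain convex penalty
        prof = np.ones_like(r)
    else:
        prof = np.tanh((r - x) / h)       # -1 below inflection, +1 above
    m = s * prof                          # required-sign profile
    viol = np.maximum(0.0, -m * f2)
    val = float(np.sum(viol ** 2))
    if not with_grad:
        return val
    grad_free = M2.T @ (2.0 * viol * (-m))
    # d prof / d x = -sech^2((r-x)/h)/h
    dprof_dx = -(1.0 - prof ** 2) / h
    dval_dx = float(np.sum(2.0 * viol * (-s * dprof_dx) * f2))
    # chain through the latent -> location squashing
    if spline.inflection_latent is not None and inflection_x is None:
        span = spline.r_cut - spline.r_low
        sig = (x - spline.r_low) / span
        dx_dlat = span * sig * (1.0 - sig)
    else:
        dx_dlat = 0.0
    return val, grad_free, dval_dx * dx_dlat


class PenaltyEngine:
    """Stacked penalty evaluation over every channel of a parameter set.

    Precomputes one sparse second- and third-derivative design matrix over
    all channels so that a full penalty evaluation during training is two
    sparse matrix-vector products.  Agrees exactly with the per-channel
    functions above (same grids, same smooth inflection profile).
    """

    def __init__(self, params, layout, config: PenaltyConfig = None,
                 sign_classes: dict = None):
        import scipy.sparse as sparse
        self.config = cfg = config or PenaltyConfig()
        self.layout = layout
        n = cfg.grid_n
        blocks2, blocks3 = [], []
        self.rows_meta = []      # per channel: (row slice, sign, latent idx,
        #                          r_low, r_cut, grid spacing)
        row0 = 0
        n_params = layout.n_params
        for (kind, pair, ch), sl in layout.spline_slices.items():
            store = params.hamiltonian if kind == "H1" else params.overlap
            spl = store[pair][ch]
            grid = spl.grid(n)
            M2 = spl.cached_design("penalty", grid, 2, free=True)
            M3 = spl.cached_design("penalty", grid, 3, free=True)
            for M, blocks in ((M2, blocks2), (M3, blocks3)):
                mm = sparse.lil_matrix((n, n_params))
                mm[:, sl] = M
                blocks.append(mm.tocsr())
            if sign_classes and (kind,) + tuple(pair) + (ch,) in sign_classes:
                sign = sign_classes[(kind,) + tuple(pair) + (ch,)]
            else:
                sign = curvature_sign_class(spl)
            lat = (layout.inflection.get((pair, ch))
                   if (kind == "S" and cfg.allow_inflection) else None)
            self.rows_meta.append((slice(row0, row0 + n), sign, lat,
                                   spl.r_low, spl.r_cut,
                                   (spl.r_cut - spl.r_low) / (n - 1)))
            row0 += n
        self.M2 = sparse.vstack(blocks2).tocsr()
        self.M2T = self.M2.T.tocsr()
        self.M3 = sparse.vstack(blocks3).tocsr()
        self.M3T = self.M3.T.tocsr()
        self.grid_r = np.concatenate(
            [np.linspace(m[3], m[4], n) for m in self.rows_meta])
        # vectorized per-row arrays for the profile computation
        nchan = len(self.rows_meta)
        self.chan_of_row = np.repeat(np.arange(nchan), n)
        self.sign_chan = np.array([m[1] for m in self.rows_meta])
        self.lat_chan = np.array(
            [m[2] if m[2] is not None else -1 for m in self.rows_meta])
        self.r_low_chan = np.array([m[3] for m in self.rows_meta])
        self.span_chan = np.array([m[4] - m[3] for m in self.rows_meta])
        self.dr_chan = np.array([m[5] for m in self.rows_meta])

    def _profiles(self, theta):
        cfg = self.config
        has_lat = self.lat_chan >= 0
        lat_val = np.where(has_lat, theta[np.maximum(self.lat_chan, 0)], 0.0)
        sig = 1.0 / (1.0 + np.exp(-lat_val))
        x_chan = self.r_low_chan + self.span_chan * sig
        h_chan = cfg.inflection_softness * self.dr_chan
        degenerate = x_chan <= self.r_low_chan + 0.5 * self.dr_chan
        active = has_lat & ~degenerate
        cr = self.chan_of_row
        rows = active[cr]                # tanh needed only on these rows
        prof = self.sign_chan[cr].copy()
        dprof = np.zeros(len(cr))
        if rows.any():
            crr = cr[rows]
            t = np.tanh((self.grid_r[rows] - x_chan[crr]) / h_chan[crr])
            prof[rows] *= t
            dx_dlat = self.span_chan * sig * (1.0 - sig)
            dprof[rows] = self.sign_chan[crr] * \
                (-(1.0 - t ** 2) / h_chan[crr]) * dx_dlat[crr]
        return prof, dprof

    def value_and_grad(self, theta):
        """Total weighted penalty and its gradient with respect to theta."""
        cfg = self.config
        f2 = self.M2 @ theta
        prof, dprof = self._profiles(theta)
        viol = np.maximum(0.0, -prof * f2)
        conv = cfg.convex_weight * float(np.sum(viol ** 2))
        grad = cfg.convex_weight * (self.M2T @ (2.0 * viol * (-prof)))
        lat_term = cfg.convex_weight * 2.0 * viol * (-f2) * dprof
        per_chan = np.bincount(self.chan_of_row, weights=lat_term,
                               minlength=len(self.sign_chan))
        for c, lat in enumerate(self.lat_chan):
            if lat >= 0:
                grad[lat] += per_chan[c]
        f3 = self.M3 @ theta
        smooth = cfg.smoothing_weight * float(np.sum(f3 ** 2))
        grad += cfg.smoothing_weight * (self.M3T @ (2.0 * f3))
        return conv + smooth, grad


def smoothing_penalty(spline: ChannelSpline, config: PenaltyConfig = None,
                      with_grad: bool = False):
    """Sum of squared third derivatives on the dense grid."""
    cfg = config or PenaltyConfig()
    if spline.degree < 4:
        raise ValueError(
            "smoothing penalty needs a continuous third derivative "
            f"(spline order >= 5); got a degree-{spline.degree} spline")
    r = spline.grid(cfg.grid_n)
    M3 = spline.cached_design("penalty", r, 3, free=True)
    f3 = M3 @ spline.free
    val = float(np.sum(f3 ** 2))
    if not with_grad:
        return val
    return val, M3.T @ (2.0 * f3)
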