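"""Loop-inverted gradient training.

The SCC and gradient-descent loops are inverted: charge fluctuations are
frozen between periodic full SCC refreshes (every ``charge_update_period``
epochs), so gradient steps never backpropagate through SCF iterations.  At
every refresh the repulsive splines and the reference energy are refit
globally by the convex program, then ADAM updates the electronic spline
coefficients, on-site energies, Hubbard parameters and inflection locations
against the weighted loss with the charges held fixed.

Batch membership is frozen for the whole run (the precompute caches depend
on it); only the batch *order* reshuffles every epoch.  A plateau scheduler
multiplies the learning rate by ``plateau_factor`` when the validation loss
has not improved by more than a relative threshold over a trailing window.
The best-validation parameter vector is retained as the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DatasetSplit
from .engine import (ParamLayout, backward, forward, precompute_batch,
                     scc_refresh, slice_cache)
from .geometry import Dataset
from .loss import LossConfig, batch_loss_and_adjoints
from .params import ParameterSet
from .qp import solve_qp
from .regularization import PenaltyConfig, PenaltyEngine
from .repulsive import RepulsiveLayout, shape_constraints


@dataclass
class TrainConfig:
    epochs: int = 2500
    batch_size: int = 10
    charge_update_period: int = 10     # epochs between SCC / repulsive refreshes
    learning_rate: float = 1e-5
    plateau_factor: float = 0.9
    plateau_window: int = 50           # epochs without improvement before a cut
    plateau_threshold: float = 1e-4    # relative improvement that resets the window
    seed: int = 0
    train_hubbards: bool = True
    scf_tol: float = 1e-7
    scf_max_iter: int = 60
    rep_constraint_grid: int = 500
    rep_ridge: float = 1e-9

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs % self.charge_update_period:
            raise ValueError("charge_update_period must divide epochs")


def make_batches(dataset: Dataset, batch_size: int, seed: int):
    """Frozen batch membership plus a per-epoch order shuffler.

    Returns (batches, shuffler): `batches` is a list of index lists fixed
    for the whole run; `shuffler()` yields a fresh batch order each call.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    batches = [perm[i:i + batch_size].tolist()
               for i in range(0, len(perm), batch_size)]
    order_rng = np.random.default_rng(seed + 1)

    def shuffler():
        return order_rng.permutation(len(batches))

    return batches, shuffler


class Adam:
    """Standard ADAM with default moment parameters."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(x)
            self.v = np.zeros_like(x)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mh = self.m / (1 - self.beta1 ** self.t)
        vh = self.v / (1 - self.beta2 ** self.t)
        return x - self.lr * mh / (np.sqrt(vh) + self.eps)


def _composition_design(geometries):
    elements = sorted({int(z) for g in geometries for z in g.atomic_numbers})
    X = np.zeros((len(geometries), len(elements) + 1))
    for i, g in enumerate(geometries):
        c = g.element_counts()
        for j, z in enumerate(elements):
            X[i, j] = c.get(z, 0)
        X[i, -1] = 1.0
    return X


def _gauge_projected_val_loss(fw, cache, lcfg, X_val):
    """Validation loss with the energy residuals projected out of the
    per-element reference gauge.

    With few held-out formulas the linear reference direction is not pinned
    by the training data (repulsive pair terms are nearly collinear with
    composition at the formula level), so raw energy residuals on held-out
    formulas drift in a direction that atomization-energy comparisons are
    invariant to.  Projecting the validation residuals onto the complement
    of the composition design makes the validation signal meaningful for
    checkpointing and plateau detection.
    """
    valid = cache.valid & (fw.ok if fw.ok is not None else True)
    nv = max(int(valid.sum()), 1)
    comps = {}
    total = 0.0
    if lcfg.w_energy > 0:
        r = np.where(valid, np.nan_to_num(fw.energy - cache.target_energy),
                     0.0)
        X = X_val[valid]
        if len(X):
            coef, *_ = np.linalg.lstsq(X, r[valid], rcond=None)
            r = r - np.where(valid, X_val @ coef, 0.0)
        scale = (np.maximum(cache.n_heavy, 1.0) if lcfg.energy_per_heavy
                 else np.ones(cache.n_conf))
        comps["energy"] = float(np.sum((lcfg.w_energy * r / scale) ** 2) / nv)
        total += comps["energy"]
    fw_masked = fw
    from .loss import batch_loss_and_adjoints
    import dataclasses
    lcfg_nd = dataclasses.replace(lcfg, w_energy=0.0)
    rest, rest_comps, *_ = batch_loss_and_adjoints(fw_masked, cache, lcfg_nd)
    comps.update({k: v for k, v in rest_comps.items() if k != "energy"})
    return total + rest, comps


@dataclass
class TrainResult:
    params: ParameterSet
    history: dict
    best_epoch: int
    best_val_loss: float


def _refit_repulsive(big_cache, rep_G, rep_h, DtD, e_elec, conv, cfg):
    D = big_cache.rep_design
    y = np.where(conv, big_cache.target_energy - e_elec, 0.0)
    Dv = D * conv[:, None].astype(float)
    P = 2.0 * (DtD - (D - Dv).T @ (D - Dv)) if not conv.all() else 2.0 * DtD
    q = -2.0 * (Dv.T @ y)
    scale = max(np.trace(P) / P.shape[0], 1.0)
    res = solve_qp(P, q, rep_G, rep_h, tol=1e-10, ridge=cfg.rep_ridge * scale)
    return res.x


def train(split: DatasetSplit, params_init: ParameterSet,
          train_config: TrainConfig = None, loss_config: LossConfig = None,
          penalty_config: PenaltyConfig = None, sign_classes: dict = None,
          target_method: str = "toy-truth", callback=None) -> TrainResult:
    """Train a parameter set against the split's train/validation targets."""
    cfg = train_config or TrainConfig()
    lcfg = loss_config or LossConfig()
    pcfg = penalty_config or PenaltyConfig()
    params = params_init.copy()
    layout = ParamLayout(params)
    rep_layout = RepulsiveLayout.from_params(params)

    batches, shuffler = make_batches(split.train, cfg.batch_size, cfg.seed)
    # one cache over the permuted training order; per-batch caches are row
    # slices sharing the frozen-charge state with the refresh
    flat = [i for idx in batches for i in idx]
    big_cache = precompute_batch([split.train[i] for i in flat], params,
                                 layout, rep_layout, target_method)
    caches = []
    off = 0
    for idx in batches:
        caches.append(slice_cache(big_cache, off, off + len(idx)))
        off += len(idx)
    val_cache = (precompute_batch(list(split.validation), params, layout,
                                  rep_layout, target_method)
                 if len(split.validation) else None)
    X_val = (_composition_design(list(split.validation))
             if val_cache is not None else None)

    theta = layout.pack(params)
    if not cfg.train_hubbards:
        hub_slice = layout.hubbard_slice
    rep_vec = rep_layout.pack(params)
    engine = PenaltyEngine(params, layout, pcfg, sign_classes)
    rep_G, rep_h = shape_constraints(params, rep_layout,
                                     cfg.rep_constraint_grid)
    DtD = big_cache.rep_design.T @ big_cache.rep_design
    adam = Adam(cfg.learning_rate)

    history = {k: [] for k in ("epoch", "train_loss", "train_data_loss",
                               "val_loss", "val_data_loss", "lr",
                               "refresh_epochs", "n_scf_failures",
                               "components", "val_components")}
    best = (np.inf, None, None, -1)
    last_improve = 0
    best_for_plateau = np.inf

    for epoch in range(cfg.epochs):
        if epoch % cfg.charge_update_period == 0:
            conv, e_elec = scc_refresh(big_cache, theta, layout,
                                       tol=cfg.scf_tol,
                                       max_iter=cfg.scf_max_iter,
                                       dq0=big_cache.frozen_dq.copy())
            rep_vec = _refit_repulsive(big_cache, rep_G, rep_h, DtD,
                                       e_elec, conv, cfg)
            # batch caches are views of big_cache: charges already current
            if val_cache is not None:
                scc_refresh(val_cache, theta, layout, tol=cfg.scf_tol,
                            max_iter=cfg.scf_max_iter,
                            dq0=val_cache.frozen_dq.copy())
            history["refresh_epochs"].append(epoch)
            history["n_scf_failures"].append(int((~conv).sum()))

        ep_data = 0.0
        ep_pen = 0.0
        for bi in shuffler():
            cache = caches[bi]
            fw = forward(cache, theta, layout, rep_vec, need_grad=True)
            data, comps, e_bar, d_bar, q_bar = batch_loss_and_adjoints(
                fw, cache, lcfg)
            grad = backward(cache, fw, layout, e_bar, d_bar, q_bar)
            pen, pgrad = engine.value_and_grad(theta)
            grad = grad + pgrad
            if not cfg.train_hubbards:
                grad[hub_slice] = 0.0
            theta = adam.step(theta, grad)
            ep_data += data
            ep_pen += pen
        nb = len(caches)
        history["epoch"].append(epoch)
        history["train_data_loss"].append(ep_data / nb)
        history["train_loss"].append((ep_data + ep_pen) / nb)
        history["components"].append(comps)
        history["lr"].append(adam.lr)

        if val_cache is not None:
            fwv = forward(val_cache, theta, layout, rep_vec, need_grad=False)
            vdata, vcomps = _gauge_projected_val_loss(fwv, val_cache, lcfg,
                                                      X_val)
            vpen, _ = engine.value_and_grad(theta)
            vloss = vdata + vpen
        else:
            vdata, vcomps, vloss = ep_data / nb, comps, (ep_data + ep_pen) / nb
        history["val_data_loss"].append(vdata)
        history["val_loss"].append(vloss)
        history["val_components"].append(vcomps)

        if vloss < best[0]:
            best = (vloss, theta.copy(), rep_vec.copy(), epoch)
        if vloss < best_for_plateau * (1 - cfg.plateau_threshold):
            best_for_plateau = vloss
            last_improve = epoch
        elif epoch - last_improve >= cfg.plateau_window:
            adam.lr *= cfg.plateau_factor
            last_improve = epoch
        if callback is not None:
            callback(epoch, theta, history)

    final_theta = best[1] if best[1] is not None else theta
    final_rep = best[2] if best[2] is not None else rep_vec
    layout.unpack(final_theta, params)
    rep_layout.unpack(final_rep, params)
    return TrainResult(params=params, history=history, best_epoch=best[3],
                       best_val_loss=best[0])
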