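"""Training loss.

A weighted sum of mean squared errors per property,

    L = sum_prop (1/N_prop) sum_i (w_prop * r_i)^2  +  penalties,

with N_prop the number of scalar residual instances of that property and
w_prop the inverse-uncertainty-like weight: 6270 / Ha for the energy
residual (taken per heavy atom), 100 / (e*angstrom) per Cartesian dipole
component, and 1 / e per atomic charge.  The energy residual is an
atomization-energy difference: the linear reference term, refit into the
repulsive model at every refresh, absorbs all per-element shifts, so
comparing totals with the reference folded in is identical to comparing
atomization energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossConfig:
    w_energy: float = 6270.0       # Ha^-1, applied to the per-heavy-atom residual
    w_dipole: float = 100.0        # (e*angstrom)^-1
    w_charge: float = 1.0          # e^-1
    energy_per_heavy: bool = True  # divide energy residual by heavy-atom count

    def __post_init__(self):
        if min(self.w_energy, self.w_dipole, self.w_charge) < 0:
            raise ValueError("loss weights must be nonnegative")


class MissingTargetError(ValueError):
    pass


def compute_loss(predictions: dict, targets: dict, loss_config: LossConfig,
                 penalties: float = 0.0):
    """Loss for aligned prediction/target arrays.

    `predictions` and `targets` carry "energy" (n,), "dipole" (n, 3) and
    "charges" (list of per-configuration arrays); `predictions` additionally
    carries "n_heavy" (n,).  Returns (total, components) with per-property
    components reported separately (penalties are a separate component).
    """
    cfg = loss_config
    comps = {}
    total = 0.0
    e_p = np.asarray(predictions["energy"], dtype=float)
    e_t = np.asarray(targets.get("energy", np.full_like(e_p, np.nan)),
                     dtype=float)
    if cfg.w_energy > 0:
        if np.any(~np.isfinite(e_t)):
            raise MissingTargetError("energy targets missing for weighted "
                                     "energy loss")
        r = e_p - e_t
        if cfg.energy_per_heavy:
            r = r / np.maximum(np.asarray(predictions["n_heavy"], float), 1.0)
        comps["energy"] = float(np.mean((cfg.w_energy * r) ** 2))
        total += comps["energy"]
    if cfg.w_dipole > 0:
        d_t = targets.get("dipole")
        if d_t is None or np.any(~np.isfinite(np.asarray(d_t, float))):
            raise MissingTargetError("dipole targets missing for weighted "
                                     "dipole loss")
        r = np.asarray(predictions["dipole"], float) - np.asarray(d_t, float)
        comps["dipole"] = float(np.mean((cfg.w_dipole * r) ** 2))
        total += comps["dipole"]
    if cfg.w_charge > 0:
        c_t = targets.get("charges")
        if c_t is None:
            raise MissingTargetError("charge targets missing for weighted "
                                     "charge loss")
        rs = []
        for cp, ct in zip(predictions["charges"], c_t):
            ct = np.asarray(ct, float)
            if np.any(~np.isfinite(ct)):
                raise MissingTargetError("charge targets missing for weighted "
                                         "charge loss")
            rs.append(np.asarray(cp, float) - ct)
        r = np.concatenate(rs)
        comps["charge"] = float(np.mean((cfg.w_charge * r) ** 2))
        total += comps["charge"]
    comps["penalty"] = float(penalties)
    total += comps["penalty"]
    return total, comps


def batch_loss_and_adjoints(fw, cache, cfg: LossConfig):
    """Vectorized loss over one forward pass, plus adjoints for backward.

    Configurations flagged invalid in the cache (SCC failures at the last
    refresh) or in the forward pass (electronic-structure pathologies) are
    excluded.  Returns (data_loss, components, e_bar, dip_bar, charge_bar).
    """
    valid = cache.valid
    if getattr(fw, "ok", None) is not None:
        valid = valid & fw.ok
    v = valid.astype(float)
    nv = max(int(v.sum()), 1)
    comps = {}
    e_bar = np.zeros(cache.n_conf)
    dip_bar = np.zeros((cache.n_conf, 3))
    q_bar = np.zeros((cache.n_conf, cache.NA))
    total = 0.0

    if cfg.w_energy > 0:
        scale = (np.maximum(cache.n_heavy, 1.0)
                 if cfg.energy_per_heavy else np.ones(cache.n_conf))
        r = np.where(v > 0, np.nan_to_num(fw.energy - cache.target_energy)
                     / scale, 0.0)
        comps["energy"] = float(np.sum((cfg.w_energy * r) ** 2) / nv)
        e_bar = 2.0 * cfg.w_energy ** 2 * r / (scale * nv)
        total += comps["energy"]
    if cfg.w_dipole > 0:
        r = np.where(v[:, None] > 0,
                     np.nan_to_num(fw.dipole - cache.target_dipole), 0.0)
        n = 3 * nv
        comps["dipole"] = float(np.sum((cfg.w_dipole * r) ** 2) / n)
        dip_bar = 2.0 * cfg.w_dipole ** 2 * r / n
        total += comps["dipole"]
    if cfg.w_charge > 0:
        m = cache.atom_valid * v[:, None]
        r = np.nan_to_num(fw.charges - cache.target_charges) * m
        n = max(int(m.sum()), 1)
        comps["charge"] = float(np.sum((cfg.w_charge * r) ** 2) / n)
        q_bar = 2.0 * cfg.w_charge ** 2 * r / n
        total += comps["charge"]
    return total, comps, e_bar, dip_bar, q_bar
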