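"""Method-comparison metrics.

Two quantum-chemical methods (here: the trained model and its reference
targets) are compared on *atomization* energies: a linear per-element
reference shift is first absorbed by least squares, and the MAE of the
remaining residuals is the reported energy metric (per molecule, per atom,
and per heavy atom).  Dipoles are compared per Cartesian component in
e*angstrom and charges per atom in e.  Outliers beyond 20 standard
deviations above the mean signed energy residual are removed in a single
pass before reporting, mirroring the bookkeeping used for large distorted
datasets where a handful of configurations fail to converge sensibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Dataset
from .repulsive import fit_reference_energy
from .scf import SCFOptions, solve_geometry
from .units import HARTREE_TO_KCAL


class MissingTargetsError(ValueError):
    pass


@dataclass
class EvaluationReport:
    n_configurations: int
    n_outliers_removed: int
    energy_mae: float            # Ha, per molecule, after reference refit
    energy_mae_kcal: float
    energy_mae_per_atom: float   # Ha / atom
    energy_mae_per_heavy_atom: float
    dipole_mae: float            # e*angstrom, per Cartesian component
    charge_mae: float            # e, per atom
    reference: object            # fitted ReferenceEnergy
    residuals: np.ndarray        # Ha, per configuration (post-refit)
    kept_mask: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n_configurations": self.n_configurations,
            "n_outliers_removed": self.n_outliers_removed,
            "energy_mae_kcal_per_mol": self.energy_mae_kcal,
            "energy_mae_ha": self.energy_mae,
            "energy_mae_per_atom_ha": self.energy_mae_per_atom,
            "energy_mae_per_heavy_atom_ha": self.energy_mae_per_heavy_atom,
            "dipole_mae_e_angstrom": self.dipole_mae,
            "charge_mae_e": self.charge_mae,
        }


def remove_outliers(errors, n_sd: float = 20.0, signed: bool = True):
    """Single-pass removal of residuals beyond mean + n_sd * SD.

    The threshold is one-sided ("above"); SD is the population standard
    deviation of the signed residuals (set ``signed=False`` to use absolute
    residuals instead).  Returns (kept mask, report dict).
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    basis = e if signed else np.abs(e)
    mu = basis.mean()
    sd = basis.std()
    thresh = mu + n_sd * sd
    kept = basis <= thresh if sd > 0 else np.ones_like(e, dtype=bool)
    report = {"n_removed": int((~kept).sum()), "threshold": float(thresh),
              "mean": float(mu), "sd": float(sd)}
    return kept, report


def predictions_from_params(params, dataset: Dataset,
                            scf_options: SCFOptions = None):
    """Run the model on every configuration; returns aligned arrays plus a
    converged mask."""
    energies, dipoles, charges, ok = [], [], [], []
    for g in dataset:
        res = solve_geometry(g, params, options=scf_options)
        energies.append(res.total_energy)
        dipoles.append(res.dipole)
        charges.append(res.charges)
        ok.append(res.converged)
    return (np.array(energies), np.array(dipoles), charges,
            np.array(ok, dtype=bool))


def evaluate(params_or_predictions, dataset: Dataset,
             target_method: str = "toy-truth", outlier_sd: float = 20.0,
             scf_options: SCFOptions = None) -> EvaluationReport:
    """Metrics table for a parameter set (or precomputed predictions).

    `params_or_predictions` is either a ParameterSet-like object (the model
    is run on every configuration) or a tuple (energies, dipoles, charges).
    """
    missing = [i for i, g in enumerate(dataset)
               if target_method not in g.targets
               or g.targets[target_method].get("energy") is None]
    if missing:
        raise MissingTargetsError(
            f"{len(missing)} configurations lack {target_method!r} targets "
            f"(first: {missing[:5]})")
    if isinstance(params_or_predictions, tuple):
        e_pred, d_pred, c_pred = params_or_predictions
        ok = np.ones(len(dataset), dtype=bool)
    else:
        e_pred, d_pred, c_pred, ok = predictions_from_params(
            params_or_predictions, dataset, scf_options)

    geoms = [g for g, k in zip(dataset, ok) if k]
    e_pred = np.asarray(e_pred)[ok]
    d_pred = np.asarray(d_pred)[ok]
    c_pred = [c for c, k in zip(c_pred, ok) if k]

    e_targ = np.array([g.targets[target_method]["energy"] for g in geoms])
    counts = [g.element_counts() for g in geoms]
    ref, residuals = fit_reference_energy(e_pred, e_targ, counts,
                                          allow_rank_deficient=True)
    # residuals of (target - pred - ref): model error after the refit
    kept, rep = remove_outliers(residuals, n_sd=outlier_sd)

    res_kept = residuals[kept]
    n_atoms = np.array([g.n_atoms for g in geoms])[kept]
    n_heavy = np.maximum(np.array([g.n_heavy for g in geoms])[kept], 1)
    mae = float(np.mean(np.abs(res_kept)))
    mae_atom = float(np.mean(np.abs(res_kept) / n_atoms))
    mae_heavy = float(np.mean(np.abs(res_kept) / n_heavy))

    d_err, c_err = [], []
    for i, (g, k) in enumerate(zip(geoms, kept)):
        if not k:
            continue
        t = g.targets[target_method]
        if t.get("dipole") is not None:
            d_err.append(np.abs(d_pred[i] - np.asarray(t["dipole"])))
        if t.get("charges") is not None:
            c_err.append(np.abs(np.asarray(c_pred[i])
                                - np.asarray(t["charges"])))
    dip_mae = float(np.mean(np.concatenate(d_err))) if d_err else np.nan
    chg_mae = float(np.mean(np.concatenate(c_err))) if c_err else np.nan

    return EvaluationReport(
        n_configurations=len(geoms), n_outliers_removed=rep["n_removed"],
        energy_mae=mae, energy_mae_kcal=mae * HARTREE_TO_KCAL,
        energy_mae_per_atom=mae_atom, energy_mae_per_heavy_atom=mae_heavy,
        dipole_mae=dip_mae, charge_mae=chg_mae, reference=ref,
        residuals=residuals, kept_mask=kept)


def report_csv(report: EvaluationReport) -> str:
    d = report.as_dict()
    lines = ["metric,value"]
    lines += [f"{k},{v}" for k, v in d.items()]
    return "\n".join(lines) + "\n"


def report_markdown(report: EvaluationReport, title: str = "Evaluation") -> str:
    d = report.as_dict()
    lines = [f"# {title}", "", "| metric | value |", "|---|---|"]
    for k, v in d.items():
        lines.append(f"| {k} | {v:.6g} |" if isinstance(v, float)
                     else f"| {k} | {v} |")
    return "\n".join(lines) + "\n"
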