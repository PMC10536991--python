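"""HDF5 dataset container.

Layout mirrors formula-grouped sampling: one group per empirical formula with

* ``atomic_numbers``  (n_atom,)
* ``coordinates``     (n_conf, n_atom, 3) angstrom
* one subgroup per target method with ``energy`` (n_conf,), ``dipole``
  (n_conf, 3) and ``charges`` (n_conf, n_atom); missing fields are stored as
  NaN so a formula group stays rectangular even when individual
  configurations are incomplete.
"""

from __future__ import annotations

from collections import defaultdict

import h5py
import numpy as np

from .geometry import Dataset, Geometry


def write_hdf5(dataset: Dataset, path):
    groups = defaultdict(list)
    for g in dataset:
        groups[g.empirical_formula].append(g)
    with h5py.File(path, "w") as f:
        for formula, geoms in groups.items():
            zs = geoms[0].atomic_numbers
            na = len(zs)
            grp = f.create_group(formula)
            grp.create_dataset("atomic_numbers", data=zs)
            grp.create_dataset(
                "coordinates", data=np.stack([g.coordinates for g in geoms]))
            methods = sorted({m for g in geoms for m in g.targets})
            for m in methods:
                sub = grp.create_group(f"targets/{m}")
                nc = len(geoms)
                e = np.full(nc, np.nan)
                dip = np.full((nc, 3), np.nan)
                ch = np.full((nc, na), np.nan)
                for i, g in enumerate(geoms):
                    t = g.targets.get(m, {})
                    if t.get("energy") is not None:
                        e[i] = t["energy"]
                    if t.get("dipole") is not None:
                        dip[i] = t["dipole"]
                    if t.get("charges") is not None:
                        ch[i] = t["charges"]
                sub.create_dataset("energy", data=e)
                sub.create_dataset("dipole", data=dip)
                sub.create_dataset("charges", data=ch)


def read_hdf5(path) -> Dataset:
    ds = Dataset()
    with h5py.File(path, "r") as f:
        for formula in sorted(f.keys()):
            grp = f[formula]
            zs = grp["atomic_numbers"][()]
            coords = grp["coordinates"][()]
            methods = sorted(grp["targets"].keys()) if "targets" in grp else []
            for i in range(coords.shape[0]):
                targets = {}
                for m in methods:
                    sub = grp[f"targets/{m}"]
                    t = {}
                    e = sub["energy"][i]
                    if np.isfinite(e):
                        t["energy"] = float(e)
                    dip = sub["dipole"][i]
                    if np.all(np.isfinite(dip)):
                        t["dipole"] = dip
                    ch = sub["charges"][i]
                    if np.all(np.isfinite(ch)):
                        t["charges"] = ch
                    if t:
                        targets[m] = t
                ds.append(Geometry(zs, coords[i], targets=targets))
    return ds
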