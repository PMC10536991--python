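"""Dataset filtering, formula-disjoint splitting, and distance analysis.

Training and testing sets are split at the level of empirical formulas so
that no formula appears on both sides; this is what makes held-out error a
test of transfer rather than of interpolation among near-identical
conformers.  Distance histograms set the spline ranges: electronic channels
run from just below the shortest observed distance out to the fixed 4.5
angstrom cutoff beyond which all channels vanish, while repulsive channels
are truncated at the nearest-neighbor shell (the first minimum of the
smoothed distance distribution).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .elements import atomic_number
from .geometry import Dataset

#: fixed upper cutoff of all electronic channels, angstrom
ELECTRONIC_CUTOFF = 4.5
#: electronic lower bound sits this far below the shortest observed distance
LOWER_MARGIN = 0.02


@dataclass
class DatasetSplit:
    train: Dataset
    validation: Dataset
    test: Dataset


def read_dataset(path, format: str = "xyz") -> Dataset:
    if format == "xyz":
        from .io_xyz import read_xyz
        return read_xyz(path)
    if format == "hdf5":
        from .io_hdf5 import read_hdf5
        return read_hdf5(path)
    raise ValueError(f"unknown format {format!r}; use 'xyz' or 'hdf5'")


def write_dataset(dataset: Dataset, path, format: str = "xyz"):
    if format == "xyz":
        from .io_xyz import write_xyz
        return write_xyz(dataset, path)
    if format == "hdf5":
        from .io_hdf5 import write_hdf5
        return write_hdf5(dataset, path)
    raise ValueError(f"unknown format {format!r}; use 'xyz' or 'hdf5'")


def filter_complete(dataset: Dataset, max_heavy_atoms: int,
                    required_fields=("energy", "dipole", "charges"),
                    method: str | None = None) -> Dataset:
    """Retain configurations with <= max_heavy_atoms heavy atoms and all
    required target fields present (under `method`, or under any single
    method when None)."""
    kept = []
    for g in dataset:
        if g.n_heavy > max_heavy_atoms:
            continue
        methods = [method] if method is not None else list(g.targets) or [None]
        ok = False
        for m in methods:
            t = g.targets.get(m, {}) if m is not None else {}
            if all(t.get(f) is not None for f in required_fields):
                ok = True
                break
        if not required_fields:
            ok = True
        if ok:
            kept.append(g)
    return Dataset(kept)


class SplitSizingError(ValueError):
    pass


def split_by_formula(dataset: Dataset, counts: dict, seed: int = 0,
                     heavy_atom_rule: dict | None = None) -> DatasetSplit:
    """Formula-disjoint train/validation/test split.

    `counts` maps split names to requested configuration counts.  Whole
    formula groups are assigned greedily in random order until each split
    reaches its request, so realized sizes match the request up to the
    granularity of formula groups.  With `heavy_atom_rule =
    {"train_max": a, "test_min": b}` only formulas whose heavy-atom count is
    <= a are eligible for train/validation and >= b for test (far-transfer).
    """
    rng = np.random.default_rng(seed)
    groups = defaultdict(list)
    for i, g in enumerate(dataset):
        groups[g.empirical_formula].append(i)
    formulas = sorted(groups)
    heavy = {f: dataset[groups[f][0]].n_heavy for f in formulas}

    order = [formulas[i] for i in rng.permutation(len(formulas))]
    want = {k: int(counts.get(k, 0)) for k in ("train", "validation", "test")}
    got = {k: [] for k in want}

    def eligible(split, formula):
        if heavy_atom_rule is None:
            return True
        if split in ("train", "validation"):
            return heavy[formula] <= heavy_atom_rule.get("train_max", 10 ** 9)
        return heavy[formula] >= heavy_atom_rule.get("test_min", 0)

    assigned = set()
    for split in ("test", "train", "validation"):  # test first: most constrained
        need = want[split]
        for f in order:
            if need <= 0:
                break
            if f in assigned or not eligible(split, f):
                continue
            got[split].extend(groups[f])
            assigned.add(f)
            need -= len(groups[f])
        if need > 0:
            avail = sum(len(groups[f]) for f in formulas
                        if f not in assigned and eligible(split, f))
            raise SplitSizingError(
                f"cannot reach {want[split]} configurations for split "
                f"{split!r}: only {avail} more available in "
                f"{sum(1 for f in formulas if f not in assigned and eligible(split, f))} "
                f"eligible formula groups")
    return DatasetSplit(train=dataset.subset(got["train"]),
                        validation=dataset.subset(got["validation"]),
                        test=dataset.subset(got["test"]))


@dataclass
class PairDistances:
    pair: tuple                 # (Z_a, Z_b) ordered, Z_a <= Z_b
    distances: np.ndarray       # angstrom
    hist: np.ndarray
    bin_edges: np.ndarray
    min_distance: float
    electronic_range: tuple     # (r_low, 4.5)
    repulsive_range: tuple      # (r_low, nearest-neighbor cutoff)


def _pair_key(za, zb):
    return (min(za, zb), max(za, zb))


def _nearest_neighbor_cutoff(dists: np.ndarray, bandwidth: float = 0.05) -> float:
    """First local minimum, after the first mode, of a Gaussian-kernel
    density estimate of the distance distribution; falls back to the maximum
    distance when the distribution is unimodal."""
    lo, hi = dists.min(), dists.max()
    if hi - lo < 1e-9:
        return float(hi)
    grid = np.linspace(lo - 3 * bandwidth, hi + 3 * bandwidth, 600)
    dens = np.exp(-0.5 * ((grid[:, None] - dists[None, :]) / bandwidth) ** 2).sum(axis=1)
    imax = int(np.argmax(dens))
    for i in range(imax + 1, len(grid) - 1):
        if dens[i] <= dens[i - 1] and dens[i] < dens[i + 1]:
            return float(grid[i])
    return float(hi)


def distance_histograms(dataset: Dataset, element_pairs, n_bins: int = 100,
                        bandwidth: float = 0.05) -> dict:
    """Per element pair: distance histogram plus suggested spline ranges.

    Returns {pair: PairDistances}; pairs absent from the dataset map to None.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    pairs = [_pair_key(atomic_number(a) if isinstance(a, str) else a,
                       atomic_number(b) if isinstance(b, str) else b)
             for (a, b) in element_pairs]
    acc = {p: [] for p in pairs}
    for g in dataset:
        dm = g.distance_matrix()
        zs = g.atomic_numbers
        n = g.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            p = _pair_key(int(zs[i]), int(zs[j]))
            if p in acc:
                acc[p].append(dm[i, j])
    out = {}
    for p in pairs:
        d = np.asarray(acc[p])
        if d.size == 0:
            out[p] = None
            continue
        hist, edges = np.histogram(d, bins=n_bins)
        rmin = float(d.min())
        r_low = rmin - LOWER_MARGIN
        rep_hi = _nearest_neighbor_cutoff(d, bandwidth)
        out[p] = PairDistances(pair=p, distances=d, hist=hist, bin_edges=edges,
                               min_distance=rmin,
                               electronic_range=(r_low, ELECTRONIC_CUTOFF),
                               repulsive_range=(r_low, rep_hi))
    return out
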