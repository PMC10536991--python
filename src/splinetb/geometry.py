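"""Molecular configurations and datasets.

A :class:`Geometry` is one molecular configuration: atomic numbers, Cartesian
coordinates in angstrom, and per-method target dictionaries (total energy in
hartree, Cartesian dipole in e*angstrom, per-atom charges in e).  A
:class:`Dataset` is an ordered list of geometries; it is the unit the
formula-disjoint splitter and the loss operate on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .elements import SUPPORTED_ELEMENTS, SYMBOLS, symbol


def hill_formula(atomic_numbers) -> str:
    """Canonical empirical formula: C first, then H, then alphabetical."""
    counts = Counter(int(z) for z in atomic_numbers)
    syms = Counter()
    for z, n in counts.items():
        syms[symbol(z)] += n
    parts = []
    order = []
    if "C" in syms:
        order.append("C")
        if "H" in syms:
            order.append("H")
        order += sorted(s for s in syms if s not in ("C", "H"))
    else:
        order = sorted(syms)
    for s in order:
        n = syms[s]
        parts.append(s if n == 1 else f"{s}{n}")
    return "".join(parts)


@dataclass
class Geometry:
    atomic_numbers: np.ndarray          # (n_atoms,) int
    coordinates: np.ndarray             # (n_atoms, 3) float, angstrom
    targets: dict = field(default_factory=dict)  # method -> {energy, dipole, charges}

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atomic_numbers), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        bad = set(self.atomic_numbers) - set(SUPPORTED_ELEMENTS)
        if bad:
            raise ValueError(f"unsupported elements: {sorted(bad)}")
        for method, t in self.targets.items():
            ch = t.get("charges")
            if ch is not None and len(ch) != len(self.atomic_numbers):
                raise ValueError(
                    f"target {method!r}: charges length {len(ch)} != atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_heavy(self) -> int:
        return int(np.sum(self.atomic_numbers != 1))

    @property
    def empirical_formula(self) -> str:
        return hill_formula(self.atomic_numbers)

    def element_counts(self) -> dict:
        return dict(Counter(int(z) for z in self.atomic_numbers))

    def distance_matrix(self) -> np.ndarray:
        """Pairwise distances in angstrom."""
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt(np.sum(d * d, axis=-1))

    def symbols(self) -> list:
        return [SYMBOLS[int(z)] for z in self.atomic_numbers]


class Dataset:
    """Ordered collection of geometries."""

    def __init__(self, geometries=()):
        self.geometries = list(geometries)

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self) -> Iterator[Geometry]:
        return iter(self.geometries)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.geometries[i])
        return self.geometries[i]

    def append(self, g: Geometry):
        self.geometries.append(g)

    def formulas(self) -> set:
        return {g.empirical_formula for g in self.geometries}

    def subset(self, indices) -> "Dataset":
        return Dataset([self.geometries[i] for i in indices])

    def elements(self) -> set:
        out = set()
        for g in self.geometries:
            out |= set(int(z) for z in g.atomic_numbers)
        return out
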