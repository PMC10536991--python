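"""Multi-frame XYZ reader/writer.

The comment line of each frame optionally carries a JSON object with the
per-method targets, e.g. ``{"toy-truth": {"energy": -1.1, "dipole": [0,0,0],
"charges": [0.1,-0.1]}}``.  Coordinates are serialized at fixed precision
(1e-6 angstrom), which bounds the round-trip error.
"""

from __future__ import annotations

import json

import numpy as np

from .elements import atomic_number
from .geometry import Dataset, Geometry


class XYZParseError(ValueError):
    pass


def _targets_to_json(targets: dict) -> str:
    enc = {}
    for method, t in targets.items():
        d = {}
        if "energy" in t and t["energy"] is not None:
            d["energy"] = float(t["energy"])
        if t.get("dipole") is not None:
            d["dipole"] = [float(x) for x in t["dipole"]]
        if t.get("charges") is not None:
            d["charges"] = [float(x) for x in t["charges"]]
        enc[method] = d
    return json.dumps(enc)


def _targets_from_json(s: str) -> dict:
    s = s.strip()
    if not s:
        return {}
    try:
        raw = json.loads(s)
    except json.JSONDecodeError:
        return {}   # plain comment line, no targets
    if not isinstance(raw, dict):
        return {}
    out = {}
    for method, t in raw.items():
        d = {}
        if "energy" in t:
            d["energy"] = float(t["energy"])
        if "dipole" in t:
            d["dipole"] = np.asarray(t["dipole"], dtype=float)
        if "charges" in t:
            d["charges"] = np.asarray(t["charges"], dtype=float)
        out[method] = d
    return out


def read_xyz(path) -> Dataset:
    ds = Dataset()
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"{path}: line {i + 1}: expected atom count, "
                                f"got {lines[i].strip()!r}") from None
        if i + 1 + n >= n_lines + 1:
            raise XYZParseError(f"{path}: frame starting at line {i + 1} is truncated")
        comment = lines[i + 1] if i + 1 < n_lines else ""
        zs, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise XYZParseError(f"{path}: line {i + 3 + j}: malformed atom record")
            zs.append(atomic_number(parts[0]))
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise XYZParseError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate") from None
        ds.append(Geometry(np.array(zs), np.array(coords),
                           targets=_targets_from_json(comment)))
        i += 2 + n
    return ds


def write_xyz(dataset: Dataset, path):
    with open(path, "w") as fh:
        for g in dataset:
            fh.write(f"{g.n_atoms}\n")
            fh.write(_targets_to_json(g.targets) + "\n")
            for sym, xyz in zip(g.symbols(), g.coordinates):
                fh.write(f"{sym} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
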