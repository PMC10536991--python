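"""Trainable parameter set.

Holds every trainable quantity of the tight-binding model: per-shell on-site
energies and Hubbard parameters, the electronic Slater-Koster channel
splines (Hamiltonian H1 and overlap S) for every element pair, the repulsive
pair splines, and the linear reference-energy coefficients that absorb
per-element shifts between quantum-chemical methods.

Channel bookkeeping convention: channels are stored on the canonical
unordered pair (za <= zb).  ``sp_sigma`` is the sigma integral with the s
orbital on the lighter element and p on the heavier; ``ps_sigma`` is the
reverse and exists only for heteronuclear pairs where the lighter element
carries p shells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .bspline import (ChannelSpline, make_electronic_spline,
                      make_repulsive_spline)
from .elements import SHELLS, symbol


@dataclass
class Shell:
    element: int
    l: str                      # "s" or "p"
    onsite_energy: float        # Ha
    hubbard: float              # Ha, > 0

    def __post_init__(self):
        if self.l not in SHELLS[self.element]:
            raise ValueError(f"element {symbol(self.element)} has no {self.l} shell")
        if self.hubbard <= 0:
            raise ValueError("hubbard must be positive")


@dataclass
class ReferenceEnergy:
    c_per_element: dict = field(default_factory=dict)   # z -> Ha
    c0: float = 0.0

    def __call__(self, element_counts: dict) -> float:
        return self.c0 + sum(n * self.c_per_element.get(z, 0.0)
                             for z, n in element_counts.items())


def canonical_pair(za: int, zb: int) -> tuple:
    return (min(za, zb), max(za, zb))


def pair_channels(za: int, zb: int) -> list:
    """Electronic channel labels for the canonical pair (za <= zb)."""
    za, zb = canonical_pair(za, zb)
    ch = ["ss_sigma"]
    a_has_p = "p" in SHELLS[za]
    b_has_p = "p" in SHELLS[zb]
    if b_has_p:
        ch.append("sp_sigma")
    if a_has_p and za != zb:
        ch.append("ps_sigma")
    if a_has_p and b_has_p:
        ch += ["pp_sigma", "pp_pi"]
    return ch


class MissingChannelError(KeyError):
    pass


@dataclass
class ParameterSet:
    shells: dict = field(default_factory=dict)      # z -> {l: Shell}
    hamiltonian: dict = field(default_factory=dict)  # (za,zb) -> {channel: ChannelSpline}
    overlap: dict = field(default_factory=dict)      # (za,zb) -> {channel: ChannelSpline}
    repulsive: dict = field(default_factory=dict)    # (za,zb) -> ChannelSpline
    reference: ReferenceEnergy = field(default_factory=ReferenceEnergy)
    metadata: dict = field(default_factory=dict)

    @property
    def elements(self) -> list:
        return sorted(self.shells)

    def shell(self, z: int, l: str) -> Shell:
        return self.shells[z][l]

    def channel(self, kind: str, za: int, zb: int, channel: str) -> ChannelSpline:
        store = self.hamiltonian if kind == "H1" else self.overlap
        pair = canonical_pair(za, zb)
        try:
            return store[pair][channel]
        except KeyError:
            raise MissingChannelError(
                f"missing {kind} channel {channel!r} for pair "
                f"{symbol(pair[0])}-{symbol(pair[1])}") from None

    def ordered_channel_values(self, kind: str, za: int, zb: int, r) -> dict:
        """Channel values for the ORDERED pair (A=za, B=zb) at distance r.

        Keys: ss_sigma, sp_sigma (s on A, p on B), ps_sigma (p on A, s on B),
        pp_sigma, pp_pi; absent channels (H has no p) are omitted.
        """
        pair = canonical_pair(za, zb)
        labels = pair_channels(*pair)
        out = {}
        for ordered_label in ("ss_sigma", "sp_sigma", "ps_sigma",
                              "pp_sigma", "pp_pi"):
            stored = resolve_channel(za, zb, ordered_label)
            if stored is None or stored not in labels:
                continue
            out[ordered_label] = float(
                self.channel(kind, za, zb, stored).eval(r)[0])
        return out

    def pairs_present(self) -> list:
        return sorted(self.hamiltonian)

    def validate_for(self, elements) -> None:
        for z in elements:
            if z not in self.shells:
                raise MissingChannelError(f"no shells for element {symbol(z)}")
        for za in elements:
            for zb in elements:
                pair = canonical_pair(za, zb)
                for ch in pair_channels(*pair):
                    self.channel("H1", *pair, ch)
                    self.channel("S", *pair, ch)

    # -- YAML checkpoints ------------------------------------------------

    def to_yaml(self, path):
        def spline_dict(sp: ChannelSpline):
            d = {"kind": sp.kind, "pair": list(sp.pair), "channel": sp.channel,
                 "r_low": float(sp.r_low), "r_cut": float(sp.r_cut),
                 "n_knots": int(sp.n_knots), "degree": int(sp.degree),
                 "free": [float(x) for x in sp.free]}
            if sp.inflection_latent is not None:
                d["inflection_latent"] = float(sp.inflection_latent)
            return d

        doc = {
            "metadata": dict(self.metadata),
            "shells": [
                {"element": z, "l": l, "onsite_energy": float(s.onsite_energy),
                 "hubbard": float(s.hubbard)}
                for z, shs in sorted(self.shells.items())
                for l, s in sorted(shs.items())],
            "reference": {"c0": float(self.reference.c0),
                          "c_per_element": {int(z): float(c) for z, c in
                                            self.reference.c_per_element.items()}},
            "hamiltonian": [spline_dict(sp) for pair in sorted(self.hamiltonian)
                            for sp in self.hamiltonian[pair].values()],
            "overlap": [spline_dict(sp) for pair in sorted(self.overlap)
                        for sp in self.overlap[pair].values()],
            "repulsive": [spline_dict(sp) for _, sp in sorted(self.repulsive.items())],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ps = cls(metadata=doc.get("metadata", {}))
        for s in doc["shells"]:
            ps.shells.setdefault(s["element"], {})[s["l"]] = Shell(
                element=s["element"], l=s["l"],
                onsite_energy=s["onsite_energy"], hubbard=s["hubbard"])
        ref = doc.get("reference", {})
        ps.reference = ReferenceEnergy(
            c_per_element={int(z): c for z, c in
                           ref.get("c_per_element", {}).items()},
            c0=ref.get("c0", 0.0))

        def load(d):
            return ChannelSpline(kind=d["kind"], pair=tuple(d["pair"]),
                                 channel=d["channel"], r_low=d["r_low"],
                                 r_cut=d["r_cut"], n_knots=d["n_knots"],
                                 degree=d["degree"],
                                 free=np.asarray(d["free"], dtype=float),
                                 inflection_latent=d.get("inflection_latent"))

        for d in doc.get("hamiltonian", []):
            sp = load(d)
            ps.hamiltonian.setdefault(tuple(sp.pair), {})[sp.channel] = sp
        for d in doc.get("overlap", []):
            sp = load(d)
            ps.overlap.setdefault(tuple(sp.pair), {})[sp.channel] = sp
        for d in doc.get("repulsive", []):
            sp = load(d)
            ps.repulsive[tuple(sp.pair)] = sp
        return ps

    def copy(self) -> "ParameterSet":
        ps = ParameterSet(metadata=dict(self.metadata))
        for z, shs in self.shells.items():
            ps.shells[z] = {l: Shell(s.element, s.l, s.onsite_energy, s.hubbard)
                            for l, s in shs.items()}
        ps.reference = ReferenceEnergy(dict(self.reference.c_per_element),
                                       self.reference.c0)
        for pair, chans in self.hamiltonian.items():
            ps.hamiltonian[pair] = {c: sp.copy() for c, sp in chans.items()}
        for pair, chans in self.overlap.items():
            ps.overlap[pair] = {c: sp.copy() for c, sp in chans.items()}
        for pair, sp in self.repulsive.items():
            ps.repulsive[pair] = sp.copy()
        return ps


def resolve_channel(za: int, zb: int, ordered_label: str):
    """Map an ordered-pair channel label to the stored canonical label.

    Returns None when the channel does not exist for the pair (e.g. any p
    channel involving H).
    """
    a_has_p = "p" in SHELLS[za]
    b_has_p = "p" in SHELLS[zb]
    if ordered_label == "ss_sigma":
        return "ss_sigma"
    if ordered_label == "sp_sigma":        # s on A, p on B
        if not b_has_p:
            return None
        if za == zb:
            return "sp_sigma"
        return "sp_sigma" if za < zb else "ps_sigma"
    if ordered_label == "ps_sigma":        # p on A, s on B
        if not a_has_p:
            return None
        if za == zb:
            return "sp_sigma"
        return "ps_sigma" if za < zb else "sp_sigma"
    if ordered_label in ("pp_sigma", "pp_pi"):
        return ordered_label if (a_has_p and b_has_p) else None
    raise ValueError(f"unknown channel label {ordered_label!r}")


def empty_parameter_set(elements, pair_ranges, n_knots_elec=100,
                        n_knots_rep=50, r_cut_elec=4.5) -> ParameterSet:
    """Scaffold a ParameterSet with zeroed splines.

    `pair_ranges` maps canonical pairs to {"electronic": (r_low, r_cut),
    "repulsive": (r_low, r_cut)}; the electronic upper cutoff defaults to
    4.5 angstrom regardless of the data.
    """
    ps = ParameterSet()
    for z in elements:
        ps.shells[z] = {}
    for za in elements:
        for zb in elements:
            pair = canonical_pair(za, zb)
            if pair in ps.hamiltonian:
                continue
            rng = pair_ranges[pair]
            r_low = rng["electronic"][0]
            ps.hamiltonian[pair] = {}
            ps.overlap[pair] = {}
            for ch in pair_channels(*pair):
                ps.hamiltonian[pair][ch] = make_electronic_spline(
                    "H1", pair, ch, r_low, r_cut_elec, n_knots_elec)
                ps.overlap[pair][ch] = make_electronic_spline(
                    "S", pair, ch, r_low, r_cut_elec, n_knots_elec)
            rep_low, rep_cut = rng["repulsive"]
            ps.repulsive[pair] = make_repulsive_spline(
                pair, rep_low, rep_cut, n_knots_rep)
    return ps
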