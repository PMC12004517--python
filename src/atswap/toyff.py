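"""Pluggable energy models for desk-scale systems.

Terms: harmonic bonds, Lennard-Jones sites, optional point charges,
fixed per-atom harmonic site wells, and occupancy-switched site wells.
No cutoffs, no periodic boundaries, no solvent model — these toys exist
to give the alchemical machinery exactly solvable reference systems.

The occupancy-switched well is how a toy expresses that binding-site
interactions follow whichever R-group currently occupies the site: the
well at ``center`` acts on each candidate atom found within ``radius``
of the center, with a spring constant belonging to that atom.  Under
either alchemical coordinate transformation the transformed occupant is
then automatically subject to its own site interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import COULOMB, ValidationError


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    k_b: float  # kcal/mol/Å²
    r0: float  # Å

    def __post_init__(self) -> None:
        if self.k_b < 0 or self.r0 < 0:
            raise ValidationError("bond parameters must be non-negative")


@dataclass(frozen=True)
class SiteWell:
    atom: int
    center: tuple[float, float, float]
    k: float  # kcal/mol/Å²


@dataclass(frozen=True)
class SwitchableWell:
    center: tuple[float, float, float]
    candidates: tuple[tuple[int, float], ...]  # (atom index, k) pairs
    radius: float = 20.0


def bond_energy(r: float, k_b: float, r0: float) -> float:
    """(k_b/2)(r − r0)², kcal/mol."""
    if r < 0:
        raise ValidationError("distance must be non-negative")
    return 0.5 * k_b * (r - r0) ** 2


def lj_energy(r: float, eps: float, sigma: float) -> float:
    """4ε[(σ/r)¹² − (σ/r)⁶], kcal/mol."""
    if r <= 0:
        raise ValidationError("Lennard-Jones singularity at r = 0")
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def coulomb_energy(r: float, qi: float, qj: float) -> float:
    if r <= 0:
        raise ValidationError("Coulomb singularity at r = 0")
    return COULOMB * qi * qj / r


@dataclass
class EnergyModel:
    bonds: list[Bond] = field(default_factory=list)
    lj: dict[int, tuple[float, float]] = field(default_factory=dict)  # atom → (ε, σ)
    charges: dict[int, float] = field(default_factory=dict)
    site_wells: list[SiteWell] = field(default_factory=list)
    switch_wells: list[SwitchableWell] = field(default_factory=list)
    exclusions: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.exclusions = {frozenset(p) for p in self.exclusions}
        for eps, sig in self.lj.values():
            if eps < 0 or sig < 0:
                raise ValidationError("LJ parameters must be non-negative")
        for w in self.site_wells:
            if w.k < 0:
                raise ValidationError("site-well k must be non-negative")

    def exclude_pairs(self, group_i, group_j) -> None:
        """Exclude all nonbonded interactions between two atom groups."""
        for i in group_i:
            for j in group_j:
                if i != j:
                    self.exclusions.add(frozenset((i, j)))

    def _nonbonded_pairs(self) -> list[tuple[int, int]]:
        atoms = sorted(set(self.lj) | set(self.charges))
        pairs = []
        for a, i in enumerate(atoms):
            for j in atoms[a + 1 :]:
                if frozenset((i, j)) not in self.exclusions:
                    pairs.append((i, j))
        return pairs

    def total_energy(self, coords: np.ndarray) -> float:
        """Sum of all terms, kcal/mol; deterministic in the input."""
        coords = np.asarray(coords, dtype=float)
        e = 0.0
        for b in self.bonds:
            r = float(np.linalg.norm(coords[b.i] - coords[b.j]))
            e += bond_energy(r, b.k_b, b.r0)
        for i, j in self._nonbonded_pairs():
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if i in self.lj and j in self.lj:
                eps = np.sqrt(self.lj[i][0] * self.lj[j][0])
                sig = 0.5 * (self.lj[i][1] + self.lj[j][1])
                if eps > 0:
                    e += lj_energy(r, eps, sig)
            if i in self.charges and j in self.charges:
                qi, qj = self.charges[i], self.charges[j]
                if qi != 0 and qj != 0:
                    e += coulomb_energy(r, qi, qj)
        for w in self.site_wells:
            d2 = float(np.sum((coords[w.atom] - np.asarray(w.center)) ** 2))
            e += 0.5 * w.k * d2
        for sw in self.switch_wells:
            center = np.asarray(sw.center)
            for atom, k in sw.candidates:
                d2 = float(np.sum((coords[atom] - center) ** 2))
                if d2 < sw.radius**2:
                    e += 0.5 * k * d2
        return e

    # convenience so an EnergyModel can be passed wherever a plain
    # energy callable is expected
    __call__ = total_energy

    def to_dict(self) -> dict:
        return {
            "bonds": [[b.i, b.j, b.k_b, b.r0] for b in self.bonds],
            "lj": {str(i): list(v) for i, v in self.lj.items()},
            "charges": {str(i): q for i, q in self.charges.items()},
            "site_wells": [
                [w.atom, list(w.center), w.k] for w in self.site_wells
            ],
            "switch_wells": [
                {
                    "center": list(w.center),
                    "candidates": [list(c) for c in w.candidates],
                    "radius": w.radius,
                }
                for w in self.switch_wells
            ],
            "exclusions": sorted(sorted(p) for p in self.exclusions),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        return cls(
            bonds=[Bond(int(i), int(j), float(k), float(r0)) for i, j, k, r0 in d.get("bonds", [])],
            lj={int(i): (float(v[0]), float(v[1])) for i, v in d.get("lj", {}).items()},
            charges={int(i): float(q) for i, q in d.get("charges", {}).items()},
            site_wells=[
                SiteWell(int(a), tuple(c), float(k)) for a, c, k in d.get("site_wells", [])
            ],
            switch_wells=[
                SwitchableWell(
                    center=tuple(w["center"]),
                    candidates=tuple((int(a), float(k)) for a, k in w["candidates"]),
                    radius=float(w.get("radius", 20.0)),
                )
                for w in d.get("switch_wells", [])
            ],
            exclusions={frozenset(p) for p in d.get("exclusions", [])},
        )

    @classmethod
    def from_json(cls, s: str) -> "EnergyModel":
        return cls.from_dict(json.loads(s))
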