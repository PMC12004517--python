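"""Flat-bottom positional restraints, the binding-site indicator, and a
simplified alignment restraint.

Convention: a flat-bottom term contributes (k/2)(r − tol)² beyond its
tolerance, so k carries units of kcal/mol/Å².  Restraints bias the
sampled ensemble but are never folded into the alchemical perturbation
energy; they are constructed to act identically on the two physical end
states (the binding-site indicator evaluates the unbound ligand as if
displaced into the site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AlchemicalPartition, ValidationError


@dataclass(frozen=True)
class PositionalRestraint:
    atom: int
    reference: tuple[float, float, float]
    tol: float = 3.0
    k: float = 25.0


@dataclass(frozen=True)
class SiteRestraint:
    """Binding-site indicator.  The site center is either an explicit
    point or the centroid of the listed (receptor) atoms; each ligand is
    represented by its anchor atom, the unbound one evaluated after
    subtracting the setup displacement d."""

    displacement: tuple[float, float, float]
    center_point: tuple[float, float, float] | None = None
    center_atoms: tuple[int, ...] | None = None
    tol: float = 5.0
    k: float = 25.0


@dataclass(frozen=True)
class AlignmentRestraint:
    """Simplified alignment term: flat-bottom on the distance between the
    displaced frame-B origin and the frame-A origin, plus harmonic
    penalties (k_theta/2)θ² on the angles between corresponding frame
    axes.  Zero when the unbound ligand's frame is displaced-and-parallel
    to the bound ligand's frame."""

    displacement: tuple[float, float, float]
    tol: float = 0.0
    k_dist: float = 25.0
    k_theta: float = 25.0


@dataclass
class RestraintSet:
    positional: list[PositionalRestraint] = field(default_factory=list)
    site: SiteRestraint | None = None
    alignment: AlignmentRestraint | None = None

    def __post_init__(self) -> None:
        for r in self.positional:
            if r.tol < 0 or r.k < 0:
                raise ValidationError("restraint tol and k must be non-negative")
        if self.site is not None and (self.site.tol < 0 or self.site.k < 0):
            raise ValidationError("restraint tol and k must be non-negative")


def flat_bottom(dist: float, tol: float, k: float) -> float:
    """0 inside the tolerance; (k/2)(dist − tol)² beyond it."""
    if dist < 0:
        raise ValidationError("distance must be non-negative")
    if dist <= tol:
        return 0.0
    return 0.5 * k * (dist - tol) ** 2


def positional_restraint_energy(coords: np.ndarray, restraints: RestraintSet) -> float:
    """Sum of flat-bottom terms over each restrained atom's displacement
    from its reference position."""
    coords = np.asarray(coords, dtype=float)
    e = 0.0
    for r in restraints.positional:
        if not 0 <= r.atom < len(coords):
            raise ValidationError(f"restrained atom {r.atom} out of range")
        d = float(np.linalg.norm(coords[r.atom] - np.asarray(r.reference)))
        e += flat_bottom(d, r.tol, r.k)
    return e


def site_center(coords: np.ndarray, site: SiteRestraint) -> np.ndarray:
    if site.center_point is not None:
        return np.asarray(site.center_point, dtype=float)
    if site.center_atoms:
        return np.mean(np.asarray(coords)[list(site.center_atoms)], axis=0)
    raise ValidationError("site restraint defines neither a point nor atoms")


def site_indicator_energy(
    coords: np.ndarray, partition: AlchemicalPartition, restraints: RestraintSet
) -> float:
    """Flat-bottom on |anchorA − center| plus |(anchorB − d) − center|:
    the unbound ligand is judged as if moved into the site."""
    if restraints.site is None:
        raise ValidationError("no site restraint defined")
    s = restraints.site
    coords = np.asarray(coords, dtype=float)
    center = site_center(coords, s)
    d = np.asarray(s.displacement, dtype=float)
    e = flat_bottom(float(np.linalg.norm(coords[partition.anchor_a] - center)), s.tol, s.k)
    e += flat_bottom(
        float(np.linalg.norm(coords[partition.anchor_b] - d - center)), s.tol, s.k
    )
    return e


def _frame_axes(coords: np.ndarray, frame: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, p, q = (np.asarray(coords)[i] for i in frame)
    v1 = p - a
    n1 = np.linalg.norm(v1)
    if n1 < 1e-12:
        raise ValidationError("degenerate alignment frame: coincident atoms")
    e1 = v1 / n1
    v2 = q - a
    v2 = v2 - np.dot(v2, e1) * e1
    n2 = np.linalg.norm(v2)
    if n2 < 1e-9:
        raise ValidationError("degenerate alignment frame: collinear atoms")
    return a, e1, v2 / n2


def alignment_restraint_energy(
    coords: np.ndarray, partition: AlchemicalPartition, restraints: RestraintSet
) -> float:
    if restraints.alignment is None:
        raise ValidationError("no alignment restraint defined")
    if partition.frame_a is None or partition.frame_b is None:
        raise ValidationError("alignment restraint requires both ligand frames")
    al = restraints.alignment
    coords = np.asarray(coords, dtype=float)
    origin_a, e1a, e2a = _frame_axes(coords, partition.frame_a)
    origin_b, e1b, e2b = _frame_axes(coords, partition.frame_b)
    d = np.asarray(al.displacement, dtype=float)
    e = flat_bottom(float(np.linalg.norm(origin_b - d - origin_a)), al.tol, al.k_dist)
    for ea, eb in ((e1a, e1b), (e2a, e2b)):
        theta = float(np.arccos(np.clip(np.dot(ea, eb), -1.0, 1.0)))
        e += 0.5 * al.k_theta * theta**2
    return e


def restraint_energy(
    coords: np.ndarray,
    restraints: RestraintSet | None,
    partition: AlchemicalPartition | None = None,
) -> float:
    """Total restraint energy of all defined terms."""
    if restraints is None:
        return 0.0
    e = positional_restraint_energy(coords, restraints)
    if restraints.site is not None:
        if partition is None:
            raise ValidationError("site restraint requires a partition")
        e += site_indicator_energy(coords, partition, restraints)
    if restraints.alignment is not None:
        if partition is None:
            raise ValidationError("alignment restraint requires a partition")
        e += alignment_restraint_energy(coords, partition, restraints)
    return e
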