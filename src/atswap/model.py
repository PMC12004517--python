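"""Domain types shared by every module.

Conventions fixed project-wide: energies in kcal/mol, lengths in Å,
temperatures in K, atom indices 0-based internally (PDB serials are
converted at the I/O boundary only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Coulomb constant, kcal Å / (mol e²)
COULOMB = 332.0637


class ValidationError(ValueError):
    """An invariant of a domain type was violated."""


class FormatError(ValueError):
    """An input file could not be parsed."""


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in (kcal/mol)⁻¹."""
    if temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


@dataclass
class Atom:
    index: int
    name: str
    element: str
    res_id: int = 1
    chain: str = "A"


@dataclass
class Structure:
    """Atoms plus Cartesian coordinates (N×3, Å)."""

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atoms)
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        indices = [a.index for a in self.atoms]
        if indices != list(range(n)):
            raise ValidationError("atom indices must be unique and contiguous 0..N-1")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class LambdaState:
    """One alchemical state: (λ, λ1, λ2, α, u0).

    λ1 and λ2 are the low- and high-energy slopes of the softplus
    coupling W, α (kcal/mol)⁻¹ sets the width of the crossover and u0
    (kcal/mol) its midpoint.
    """

    lam: float
    lam1: float
    lam2: float
    alpha: float
    u0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError(f"lam must be in [0,1], got {self.lam}")
        if self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("lam1", "lam2", "alpha", "u0"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class SoftcoreParams:
    """Soft-core cap: identity below u_c, asymptote u_max above."""

    u_max: float = 200.0
    u_c: float = 100.0
    a: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if not self.u_max > self.u_c >= 0:
            raise ValidationError(
                f"need u_max > u_c >= 0, got u_max={self.u_max}, u_c={self.u_c}"
            )
        if self.a <= 0:
            raise ValidationError(f"a must be > 0, got {self.a}")


@dataclass
class AlchemicalPartition:
    """Decomposition of the system into receptor, the two ligands'
    common and variable regions, and solvent.

    ``common_a[i]`` is mapped one-to-one to ``common_b[i]``; the anchor
    atoms are the common-region atoms to which the variable R-groups
    attach and must be mapped to each other.
    """

    receptor: frozenset[int]
    common_a: list[int]
    common_b: list[int]
    variable_a: frozenset[int]
    variable_b: frozenset[int]
    solvent: frozenset[int]
    anchor_a: int
    anchor_b: int
    frame_a: tuple[int, int, int] | None = None
    frame_b: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.receptor = frozenset(self.receptor)
        self.variable_a = frozenset(self.variable_a)
        self.variable_b = frozenset(self.variable_b)
        self.solvent = frozenset(self.solvent)
        self.common_a = list(self.common_a)
        self.common_b = list(self.common_b)

    def validate(self, n_atoms: int) -> None:
        groups = {
            "receptor": set(self.receptor),
            "commonA": set(self.common_a),
            "commonB": set(self.common_b),
            "variableA": set(self.variable_a),
            "variableB": set(self.variable_b),
            "solvent": set(self.solvent),
        }
        if len(self.common_a) != len(set(self.common_a)):
            raise ValidationError("commonA contains duplicate atoms")
        if len(self.common_b) != len(set(self.common_b)):
            raise ValidationError("commonB contains duplicate atoms")
        if len(self.common_a) != len(self.common_b):
            raise ValidationError("common regions differ in size")
        if len(self.common_a) < 1:
            raise ValidationError("common regions must contain at least one atom")
        names = list(groups)
        for i, gi in enumerate(names):
            for gj in names[i + 1 :]:
                overlap = groups[gi] & groups[gj]
                if overlap:
                    raise ValidationError(
                        f"{gi} and {gj} overlap on atoms {sorted(overlap)}"
                    )
        union = set().union(*groups.values())
        if union != set(range(n_atoms)):
            raise ValidationError(
                "partition must cover all atoms exactly once "
                f"(covers {len(union)} of {n_atoms})"
            )
        if self.anchor_a not in groups["commonA"]:
            raise ValidationError("anchorA must belong to commonA")
        if self.anchor_b not in groups["commonB"]:
            raise ValidationError("anchorB must belong to commonB")
        ia = self.common_a.index(self.anchor_a)
        if self.common_b[ia] != self.anchor_b:
            raise ValidationError("anchor atoms must be mapped to each other")
        for frame, anchor, label in (
            (self.frame_a, self.anchor_a, "frameA"),
            (self.frame_b, self.anchor_b, "frameB"),
        ):
            if frame is not None:
                if len(frame) != 3:
                    raise ValidationError(f"{label} must list exactly 3 atoms")
                if frame[0] != anchor:
                    raise ValidationError(
                        f"first atom of {label} must be the anchor atom"
                    )

    @property
    def mapping(self) -> dict[int, int]:
        """Bijection commonA atom → commonB atom."""
        return dict(zip(self.common_a, self.common_b))

    def ligand_a(self) -> set[int]:
        return set(self.common_a) | set(self.variable_a)

    def ligand_b(self) -> set[int]:
        return set(self.common_b) | set(self.variable_b)


@dataclass
class SampleSet:
    """Per-state time series of soft-core perturbation energies.

    ``u_sc[k]`` holds the samples collected while a replica occupied
    alchemical state ``k``; ``u0[k]`` the corresponding unperturbed
    (physical) potential energies, kept for diagnostics only since they
    cancel in all state differences.
    """

    states: list[LambdaState]
    temperature: float
    softcore: SoftcoreParams
    sweeps: list[np.ndarray] = field(default_factory=list)
    u_sc: list[np.ndarray] = field(default_factory=list)
    u0: list[np.ndarray] = field(default_factory=list)
    equil_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValidationError("at least one state required")
        if not self.sweeps:
            self.sweeps = [np.empty(0, dtype=int) for _ in self.states]
            self.u_sc = [np.empty(0) for _ in self.states]
            self.u0 = [np.empty(0) for _ in self.states]
        if not (len(self.sweeps) == len(self.u_sc) == len(self.u0) == len(self.states)):
            raise ValidationError("per-state arrays must match the state count")
        self.sweeps = [np.asarray(s, dtype=int) for s in self.sweeps]
        self.u_sc = [np.asarray(u, dtype=float) for u in self.u_sc]
        self.u0 = [np.asarray(u, dtype=float) for u in self.u0]
        tol = 1e-9
        for k, u in enumerate(self.u_sc):
            if u.size and np.max(u) > self.softcore.u_max + tol:
                raise ValidationError(
                    f"state {k}: u_sc exceeds the soft-core bound u_max="
                    f"{self.softcore.u_max}"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def counts(self) -> np.ndarray:
        return np.array([u.size for u in self.u_sc])


@dataclass
class FreeEnergyNetwork:
    """Directed ΔΔG edges between ligand labels, with 1σ uncertainties."""

    edges: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, ddg: float, sigma: float = 0.0) -> None:
        a, b = _norm_label(a), _norm_label(b)
        if a == b:
            raise ValidationError(f"self-edge {a}->{b} not allowed")
        if (a, b) in self.edges:
            raise ValidationError(f"duplicate edge {a}->{b}")
        self.edges[(a, b)] = (float(ddg), float(sigma))

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def ddg(self, a: str, b: str) -> float:
        key = (_norm_label(a), _norm_label(b))
        if key not in self.edges:
            raise ValidationError(f"missing edge {key[0]}->{key[1]}")
        return self.edges[key][0]

    def sigma(self, a: str, b: str) -> float:
        key = (_norm_label(a), _norm_label(b))
        if key not in self.edges:
            raise ValidationError(f"missing edge {key[0]}->{key[1]}")
        return self.edges[key][1]

    def has_edge(self, a: str, b: str) -> bool:
        return (_norm_label(a), _norm_label(b)) in self.edges


def _norm_label(label: str) -> str:
    # "A0 V" and "A0V" refer to the same mutant
    return "".join(str(label).split())


def infer_element(atom_name: str) -> str:
    """Best-effort element from an atom name's first alphabetic character."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    warnings.warn(f"could not infer element from atom name {atom_name!r}; using 'X'")
    return "X"
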