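"""The two alchemical coordinate transformations and the perturbation
energy they induce.

The whole-ligand transfer translates ligand A by a fixed displacement d
and ligand B by −d, exchanging the bound and unbound positions.  The
swap-and-displace variant instead swaps the coordinates of the mapped
common-region atoms and rigidly translates only the variable R-groups,
A by the instantaneous anchor-anchor displacement d_BA and B by −d_BA.
Because the swap is a permutation and d_BA is recomputed from the input
coordinates, the swap-and-displace transform is an involution, and every
distance between a variable-region atom and its own anchor is preserved
exactly (the anchor's image is the mapped anchor at anchor + d_BA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AlchemicalPartition, ValidationError


@dataclass(frozen=True)
class Displacement:
    vector: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.vector) != 3 or not np.all(np.isfinite(self.vector)):
            raise ValidationError("displacement must be a finite 3-vector")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


def displacement_vector(
    coords: np.ndarray, partition: AlchemicalPartition
) -> Displacement:
    """d_BA: position of anchor B relative to anchor A."""
    d = coords[partition.anchor_b] - coords[partition.anchor_a]
    return Displacement(tuple(float(x) for x in d))


def ats_transform(coords: np.ndarray, partition: AlchemicalPartition) -> np.ndarray:
    """Swap mapped common-region coordinates; translate variable atoms of
    A by d_BA and of B by −d_BA.  Receptor and solvent rows untouched."""
    coords = np.asarray(coords, dtype=float)
    d = displacement_vector(coords, partition).as_array()
    out = coords.copy()
    ia = np.asarray(partition.common_a, dtype=int)
    ib = np.asarray(partition.common_b, dtype=int)
    out[ia] = coords[ib]
    out[ib] = coords[ia]
    va = sorted(partition.variable_a)
    vb = sorted(partition.variable_b)
    if va:
        out[va] = coords[va] + d
    if vb:
        out[vb] = coords[vb] - d
    return out


def atm_transform(
    coords: np.ndarray, partition: AlchemicalPartition, d: Displacement
) -> np.ndarray:
    """Translate all atoms of ligand A by +d and of ligand B by −d."""
    coords = np.asarray(coords, dtype=float)
    dv = d.as_array()
    out = coords.copy()
    la = sorted(partition.ligand_a())
    lb = sorted(partition.ligand_b())
    out[la] = coords[la] + dv
    out[lb] = coords[lb] - dv
    return out


def perturbation_energy(
    coords: np.ndarray,
    partition: AlchemicalPartition,
    energy_model,
    mode: str = "ats",
    d: Displacement | None = None,
) -> float:
    """u = U(transformed coords) − U(input coords), kcal/mol.

    ``energy_model`` is either a callable coords → energy or an object
    with a ``total_energy`` method.  mode='ats' uses the swap-and-
    displace transform (any supplied d is ignored); mode='atm' requires
    an explicit fixed displacement d.
    """
    energy = getattr(energy_model, "total_energy", energy_model)
    if mode == "ats":
        transformed = ats_transform(coords, partition)
    elif mode == "atm":
        if d is None:
            raise ValidationError("mode='atm' requires an explicit displacement d")
        transformed = atm_transform(coords, partition, d)
    else:
        raise ValidationError(f"unknown mode {mode!r} (expected 'ats' or 'atm')")
    u0 = float(energy(coords))
    u1 = float(energy(transformed))
    if not (np.isfinite(u0) and np.isfinite(u1)):
        raise ValidationError("non-finite energy at a transformation endpoint")
    return u1 - u0
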