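"""Desk-scale congeneric systems with analytically known relative
binding free energies, and network fixtures.

The toy pair emulates the physical setup of a swap-based relative
binding free energy calculation: a one-site receptor, two two-bead
ligands (an anchor bead and an R-group bead joined by a harmonic bond of
zero rest length), the first ligand bound at the receptor site and the
second displaced 40 Å away along y in the "bulk".  The receptor bead is
fixed; the anchors are held at their sites by stiff positional
restraints so the single-ligand partition functions factor into
independent Gaussians.  Binding-site interactions are expressed by
occupancy-switched harmonic wells centered on the site that act on
whichever bead currently occupies the site region — with the spring
constant belonging to that bead — so the site interaction follows the
alchemical coordinate transformation exactly as a physical binding
interaction would.  Ligand-ligand nonbonded interactions are absent.

With every coupled degree of freedom Gaussian, the relative binding
free energy has the closed form

    ΔΔG = (3/(2β)) · ln[(k_bond + k_siteB)/(k_bond + k_siteA)] ,

the free energy of swapping which R-group bead feels which site well:
bound bead X fluctuates with total stiffness k_bond + k_siteX (bond and
site well share their center), unbound beads with k_bond, and each 3-D
Gaussian contributes (3/(2β))·ln k to the free energy.  The stiff anchor
restraints perturb this by less than 0.01 kcal/mol at the default
1000 kcal/mol/Å².
"""

from __future__ import annotations

import numpy as np

from .model import AlchemicalPartition, Atom, Structure, ValidationError, beta
from .restraints import PositionalRestraint, RestraintSet, SiteRestraint
from .toyff import Bond, EnergyModel, SwitchableWell
from .model import FreeEnergyNetwork

#: setup displacement of the unbound ligand, Å
TOY_DISPLACEMENT = (0.0, 40.0, 0.0)

#: default stiffness of the anchor positional restraints, kcal/mol/Å²
ANCHOR_RESTRAINT_K = 1000.0

#: common-region (anchor) site-well stiffness, identical for both
#: ligands so it cancels from the relative binding free energy
ANCHOR_WELL_K = 5.0


def make_toy_pair(
    k_bond: float = 10.0,
    k_site_a: float = 10.0,
    k_site_b: float = 40.0,
    seed: int = 0,
) -> tuple[Structure, AlchemicalPartition, EnergyModel, RestraintSet]:
    """Build the harmonic congeneric pair.

    Atoms: 0 receptor site bead (frozen by the samplers), 1 anchor A,
    2 R-group bead A (bound, in the site well), 3 anchor B, 4 R-group
    bead B (unbound).  The R beads start at their well centers plus a
    small seeded jitter.
    """
    for name, k in (("k_bond", k_bond), ("k_site_a", k_site_a), ("k_site_b", k_site_b)):
        if k <= 0:
            raise ValidationError(f"{name} must be > 0, got {k}")
    rng = np.random.default_rng(seed)
    site = np.zeros(3)
    d = np.asarray(TOY_DISPLACEMENT)
    coords = np.array(
        [
            site,
            site,
            site + rng.normal(0.0, 0.1, 3),
            site + d,
            site + d + rng.normal(0.0, 0.1, 3),
        ]
    )
    atoms = [
        Atom(0, "RC", "C", res_id=1, chain="R"),
        Atom(1, "CA", "C", res_id=2, chain="L"),
        Atom(2, "RA", "C", res_id=2, chain="L"),
        Atom(3, "CB", "C", res_id=3, chain="M"),
        Atom(4, "RB", "C", res_id=3, chain="M"),
    ]
    structure = Structure(atoms=atoms, coords=coords)
    partition = AlchemicalPartition(
        receptor=frozenset({0}),
        common_a=[1],
        common_b=[3],
        variable_a=frozenset({2}),
        variable_b=frozenset({4}),
        solvent=frozenset(),
        anchor_a=1,
        anchor_b=3,
    )
    partition.validate(structure.n_atoms)
    model = EnergyModel(
        bonds=[Bond(1, 2, k_bond, 0.0), Bond(3, 4, k_bond, 0.0)],
        switch_wells=[
            # R-group site interaction: the constant follows the occupant
            SwitchableWell(
                center=tuple(site), candidates=((2, k_site_a), (4, k_site_b))
            ),
            # common-region site interaction, identical for both ligands
            SwitchableWell(
                center=tuple(site),
                candidates=((1, ANCHOR_WELL_K), (3, ANCHOR_WELL_K)),
            ),
        ],
    )
    # no ligand-ligand nonbonded terms exist; record the exclusion anyway
    model.exclude_pairs(partition.ligand_a(), partition.ligand_b())
    restraints = RestraintSet(
        positional=[
            PositionalRestraint(1, tuple(site), tol=0.0, k=ANCHOR_RESTRAINT_K),
            PositionalRestraint(3, tuple(site + d), tol=0.0, k=ANCHOR_RESTRAINT_K),
        ],
        site=SiteRestraint(
            displacement=TOY_DISPLACEMENT, center_atoms=(0,), tol=5.0, k=25.0
        ),
    )
    return structure, partition, model, restraints


def analytic_rbfe(
    k_bond: float, k_site_a: float, k_site_b: float, temperature: float = 300.0
) -> float:
    """Closed-form ΔΔG = ΔG_b(B) − ΔG_b(A) of the toy pair, kcal/mol.

    (3/(2β))·ln[(k_bond + k_siteB)/(k_bond + k_siteA)]: each bound R
    bead is a 3-D Gaussian of stiffness k_bond + k_site (bond and site
    well are concentric), each unbound bead one of stiffness k_bond, and
    the unbound factors cancel between the two ligands.
    """
    for name, k in (("k_bond", k_bond), ("k_site_a", k_site_a), ("k_site_b", k_site_b)):
        if k <= 0:
            raise ValidationError(f"{name} must be > 0, got {k}")
    b = beta(temperature)
    return 1.5 / b * np.log((k_bond + k_site_b) / (k_bond + k_site_a))


def analytic_rbfe_restrained(
    k_bond: float,
    k_site_a: float,
    k_site_b: float,
    temperature: float = 300.0,
    k_restraint: float = ANCHOR_RESTRAINT_K,
    k_anchor_well: float = ANCHOR_WELL_K,
) -> float:
    """Exact ΔΔG of the toy pair including the anchor degrees of freedom.

    The bound ligand's (anchor, R-bead) pair is a coupled 3-D Gaussian
    with per-dimension Hessian [[K+k_b, −k_b], [−k_b, k_b+k_site]],
    where K = k_restraint + k_anchor_well is the total anchor stiffness;
    the unbound pair has Hessian determinant K·k_b, identical for both
    ligands.  Hence

        ΔΔG = (3/(2β)) · ln[ ((K+k_b)(k_b+k_siteB) − k_b²)
                           / ((K+k_b)(k_b+k_siteA) − k_b²) ] ,

    which tends to the ideal ``analytic_rbfe`` as K → ∞ and differs from
    it by < 0.01 kcal/mol at the default stiffnesses.
    """
    b = beta(temperature)
    big_k = k_restraint + k_anchor_well
    det_b = (big_k + k_bond) * (k_bond + k_site_b) - k_bond**2
    det_a = (big_k + k_bond) * (k_bond + k_site_a) - k_bond**2
    return 1.5 / b * np.log(det_b / det_a)


def make_selftransform_pair(
    seed: int = 0, k_bond: float = 10.0, k_site: float = 10.0
) -> tuple[Structure, AlchemicalPartition, EnergyModel, RestraintSet]:
    """Toy pair whose second ligand is an exact conformational copy of
    the first (identical spring constants): the true ΔΔG is 0 by
    symmetry, which exercises the exactness of the swap estimator."""
    return make_toy_pair(k_bond=k_bond, k_site_a=k_site, k_site_b=k_site, seed=seed)


def make_network_fixture(
    n_nodes: int,
    true_values,
    noise_sigma: float,
    seed: int = 0,
) -> FreeEnergyNetwork:
    """Directional network whose edges are differences of node potentials
    plus independent Gaussian noise; with zero noise every hysteresis and
    cycle closure vanishes exactly."""
    values = np.asarray(true_values, dtype=float)
    if values.size != n_nodes:
        raise ValidationError("true_values must supply one potential per node")
    rng = np.random.default_rng(seed)
    net = FreeEnergyNetwork()
    labels = [f"L{i}" for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            ddg = values[j] - values[i] + rng.normal(0.0, noise_sigma)
            net.add_edge(labels[i], labels[j], ddg, noise_sigma)
    return net
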