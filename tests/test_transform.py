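"""Coordinate transformations and the induced perturbation energy."""

import numpy as np
import pytest

from atswap.model import AlchemicalPartition
from atswap.synthetic import make_toy_pair
from atswap.transform import (
    Displacement,
    atm_transform,
    ats_transform,
    displacement_vector,
    perturbation_energy,
)


def _partition_7():
    # 0 receptor; ligand A = common [1,2] + variable {3}; B = [4,5] + {6}
    return AlchemicalPartition(
        receptor=frozenset({0}),
        common_a=[1, 2],
        common_b=[4, 5],
        variable_a=frozenset({3}),
        variable_b=frozenset({6}),
        solvent=frozenset(),
        anchor_a=2,
        anchor_b=5,
    )


def _coords_7():
    return np.array(
        [
            [9.0, 9.0, 9.0],  # receptor
            [0.0, 0.0, 1.0],  # commonA[0]
            [0.0, 0.0, 0.0],  # anchor A
            [1.0, 0.0, 0.0],  # variable A
            [3.5, 1.0, -2.0],  # commonB[0]
            [3.0, 0.0, 0.0],  # anchor B
            [4.0, 1.0, 0.0],  # variable B
        ]
    )


class TestDisplacementVector:
    @pytest.mark.parametrize(
        "pa, pb, expected",
        [
            ((0, 0, 0), (3, 0, 0), (3, 0, 0)),
            ((1, 1, 1), (1, 1, 1), (0, 0, 0)),
            ((1, 2, 3), (-1, 0, 5), (-2, -2, 2)),
        ],
    )
    def test_anchor_difference(self, pa, pb, expected):
        coords = _coords_7()
        coords[2] = pa
        coords[5] = pb
        d = displacement_vector(coords, _partition_7())
        assert d.vector == expected


class TestAtsTransform:
    def test_variable_atoms_translate_by_anchor_displacement(self):
        out = ats_transform(_coords_7(), _partition_7())
        assert np.allclose(out[3], [4.0, 0.0, 0.0])  # +d_BA = (3,0,0)
        assert np.allclose(out[6], [1.0, 1.0, 0.0])  # −d_BA

    def test_common_region_coordinates_swap(self):
        coords = _coords_7()
        out = ats_transform(coords, _partition_7())
        assert np.array_equal(out[1], coords[4])
        assert np.array_equal(out[4], coords[1])
        assert np.array_equal(out[2], coords[5])
        assert np.array_equal(out[5], coords[2])

    def test_receptor_and_solvent_rows_bit_identical(self):
        coords = _coords_7()
        out = ats_transform(coords, _partition_7())
        assert np.array_equal(out[0], coords[0])

    def test_involution(self, rng):
        part = _partition_7()
        for _ in range(20):
            coords = _coords_7() + rng.normal(0, 2.0, size=(7, 3))
            back = ats_transform(ats_transform(coords, part), part)
            assert np.max(np.abs(back - coords)) < 1e-12

    def test_common_region_multiset_preserved(self, rng):
        part = _partition_7()
        coords = _coords_7() + rng.normal(0, 1.0, size=(7, 3))
        out = ats_transform(coords, part)
        common = [1, 2, 4, 5]
        before = sorted(map(tuple, coords[common]))
        after = sorted(map(tuple, out[common]))
        assert before == after

    def test_anchor_to_variable_distances_preserved(self, rng):
        part = _partition_7()
        for _ in range(10):
            coords = _coords_7() + rng.normal(0, 2.0, size=(7, 3))
            out = ats_transform(coords, part)
            # the variable atom's bond to its own anchor is preserved:
            # the anchor's image (the mapped anchor's old position) sits
            # at anchor + d_BA, exactly the variable atom's shift
            before_a = np.linalg.norm(coords[3] - coords[2])
            after_a = np.linalg.norm(out[3] - out[2])
            assert after_a == pytest.approx(before_a, abs=1e-9)
            before_b = np.linalg.norm(coords[6] - coords[5])
            after_b = np.linalg.norm(out[6] - out[5])
            assert after_b == pytest.approx(before_b, abs=1e-9)

    def test_agrees_with_whole_ligand_transform_for_identical_conformers(self):
        # ligand B an exact translated copy of A: the swap is then the
        # same map as translating each whole ligand by ±d
        coords = _coords_7()
        d = np.array([3.0, 0.0, 0.0])
        coords[4] = coords[1] + d
        coords[6] = coords[3] + d
        part = _partition_7()
        out_ats = ats_transform(coords, part)
        out_atm = atm_transform(coords, part, Displacement(tuple(d)))
        assert np.allclose(out_ats, out_atm, atol=1e-12)


class TestAtmTransform:
    def test_fixed_displacement_moves_whole_ligands(self):
        coords = _coords_7()
        d = Displacement((0.0, 0.0, -45.0))
        out = atm_transform(coords, _partition_7(), d)
        assert np.allclose(out[1], coords[1] + [0, 0, -45])
        assert np.allclose(out[3], coords[3] + [0, 0, -45])
        assert np.allclose(out[6], coords[6] - [0, 0, -45])
        assert np.array_equal(out[0], coords[0])

    def test_zero_displacement_is_identity(self):
        coords = _coords_7()
        out = atm_transform(coords, _partition_7(), Displacement((0, 0, 0)))
        assert np.array_equal(out, coords)

    def test_applying_twice_doubles_the_shift(self):
        coords = _coords_7()
        d = Displacement((1.0, 2.0, 3.0))
        part = _partition_7()
        out = atm_transform(atm_transform(coords, part, d), part, d)
        assert np.allclose(out[3], coords[3] + [2, 4, 6])


def _independent_perturbation(coords, partition, model):
    """Brute-force oracle: rebuild the transformed configuration with
    explicit per-atom rules and re-sum every energy term by hand."""
    coords = np.asarray(coords, dtype=float)
    d = coords[partition.anchor_b] - coords[partition.anchor_a]
    new = coords.copy()
    for i, j in zip(partition.common_a, partition.common_b):
        new[i] = coords[j]
        new[j] = coords[i]
    for k in partition.variable_a:
        new[k] = coords[k] + d
    for k in partition.variable_b:
        new[k] = coords[k] - d

    def energy(c):
        e = 0.0
        for b in model.bonds:
            r = np.linalg.norm(c[b.i] - c[b.j])
            e += 0.5 * b.k_b * (r - b.r0) ** 2
        for w in model.site_wells:
            e += 0.5 * w.k * np.sum((c[w.atom] - np.asarray(w.center)) ** 2)
        for sw in model.switch_wells:
            for atom, k in sw.candidates:
                dd = np.sum((c[atom] - np.asarray(sw.center)) ** 2)
                if dd < sw.radius**2:
                    e += 0.5 * k * dd
        return e

    return energy(new) - energy(coords)


class TestPerturbationEnergy:
    def test_translated_copy_gives_zero(self):
        # B an exact translated copy of A, no A-B interactions: by
        # symmetry the swap changes nothing energetically
        structure, partition, model, _ = make_toy_pair(seed=0)
        coords = structure.coords.copy()
        coords[4] = coords[2] + [0.0, 40.0, 0.0]  # same internal conformation
        # make site wells symmetric so the two ligands are identical
        model.switch_wells[0] = type(model.switch_wells[0])(
            center=model.switch_wells[0].center,
            candidates=((2, 10.0), (4, 10.0)),
        )
        u = perturbation_energy(coords, partition, model, mode="ats")
        assert u == pytest.approx(0.0, abs=1e-9)

    def test_pure_core_swap_of_identical_conformers_is_zero(self):
        part = AlchemicalPartition(
            receptor=frozenset({0}),
            common_a=[1, 2],
            common_b=[3, 4],
            variable_a=frozenset(),
            variable_b=frozenset(),
            solvent=frozenset(),
            anchor_a=1,
            anchor_b=3,
        )
        coords = np.array(
            [[9.0, 9, 9], [0, 0, 0], [1, 0, 0], [0, 5, 0], [1, 5, 0]]
        )
        from atswap.toyff import Bond, EnergyModel

        model = EnergyModel(bonds=[Bond(1, 2, 10.0, 1.0), Bond(3, 4, 10.0, 1.0)])
        u = perturbation_energy(coords, part, model, mode="ats")
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        structure, partition, model, _ = make_toy_pair(seed=3)
        for _ in range(25):
            coords = structure.coords + rng.normal(0, 0.5, size=(5, 3))
            u = perturbation_energy(coords, partition, model, mode="ats")
            assert u == pytest.approx(
                _independent_perturbation(coords, partition, model), abs=1e-10
            )

    def test_atm_requires_displacement(self):
        structure, partition, model, _ = make_toy_pair(seed=0)
        with pytest.raises(Exception, match="displacement|d"):
            perturbation_energy(structure.coords, partition, model, mode="atm")
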