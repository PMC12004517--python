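"""Domain types and file round-trips."""

import numpy as np
import pytest

from atswap.io import (
    read_partition,
    read_pdb,
    read_samples,
    read_schedule,
    write_partition,
    write_pdb,
    write_samples,
    write_schedule,
)
from atswap.model import (
    AlchemicalPartition,
    Atom,
    FormatError,
    FreeEnergyNetwork,
    LambdaState,
    SampleSet,
    SoftcoreParams,
    Structure,
    ValidationError,
)

PDB_3 = """\
ATOM      1  C1  LIG A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  O1  LIG A   1      -1.500   0.250   9.125  1.00  0.00           O
HETATM    3  ZN  ZN  B   2       0.000   0.000  -4.750  1.00  0.00          ZN
"""


def _structure(n=7):
    atoms = [Atom(i, f"C{i}", "C") for i in range(n)]
    return Structure(atoms=atoms, coords=np.zeros((n, 3)))


def _partition(**overrides):
    kw = dict(
        receptor=frozenset({0}),
        common_a=[1, 2],
        common_b=[4, 5],
        variable_a=frozenset({3}),
        variable_b=frozenset({6}),
        solvent=frozenset(),
        anchor_a=2,
        anchor_b=5,
    )
    kw.update(overrides)
    return AlchemicalPartition(**kw)


class TestPdb:
    def test_read_parses_records(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_3)
        s = read_pdb(p)
        assert s.n_atoms == 3
        assert np.allclose(s.coords[0], [1.0, 2.0, 3.0])
        assert np.allclose(s.coords[2], [0.0, 0.0, -4.75])
        assert [a.index for a in s.atoms] == [0, 1, 2]
        assert s.atoms[1].element == "O"

    def test_round_trip_identity(self, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        p1.write_text(PDB_3)
        s1 = read_pdb(p1)
        write_pdb(s1, p2)
        s2 = read_pdb(p2)
        assert np.array_equal(s1.coords, s2.coords)
        assert [a.name for a in s1.atoms] == [a.name for a in s2.atoms]
        assert [a.chain for a in s1.atoms] == [a.chain for a in s2.atoms]

    def test_truncated_coordinate_is_format_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  C1  LIG A   1       1.000   2.0\n")
        with pytest.raises(FormatError, match="line 1"):
            read_pdb(p)

    def test_garbled_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        good = PDB_3.splitlines()[0]
        bad = good[:30] + "  xx.yyy" + good[38:]
        p.write_text(good + "\n" + bad + "\n")
        with pytest.raises(FormatError, match="line 2"):
            read_pdb(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(FormatError, match="no ATOM"):
            read_pdb(p)

    def test_write_rejects_overflow_and_nonfinite(self, tmp_path):
        s = _structure(1)
        s.coords = np.array([[10000.0, 0, 0]])
        with pytest.raises(ValidationError, match="10000"):
            write_pdb(s, tmp_path / "x.pdb")
        s.coords = np.array([[np.nan, 0, 0]])
        with pytest.raises(ValidationError, match="finite"):
            write_pdb(s, tmp_path / "x.pdb")

    def test_origin_atom_formats_three_decimals(self, tmp_path):
        s = _structure(1)
        write_pdb(s, tmp_path / "o.pdb")
        line = (tmp_path / "o.pdb").read_text().splitlines()[0]
        assert "0.000   0.000   0.000" in line


class TestPartition:
    def test_round_trip(self, tmp_path):
        part = _partition()
        s = _structure()
        part.validate(s.n_atoms)
        write_partition(part, tmp_path / "p.tsv")
        again = read_partition(tmp_path / "p.tsv", s)
        assert again.common_a == part.common_a
        assert again.common_b == part.common_b
        assert again.anchor_a == part.anchor_a
        assert again.variable_b == part.variable_b

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (dict(common_b=[4]), "differ in size"),
            (dict(common_b=[4, 4]), "duplicate"),
            (dict(variable_a=frozenset({2, 3})), "overlap"),
            (dict(anchor_a=3), "anchorA must belong"),
            (dict(anchor_b=4), "mapped to each other"),
            (dict(solvent=frozenset({6})), "overlap"),
            (dict(variable_b=frozenset()), "cover all atoms"),
            (dict(frame_a=(1, 2, 3)), "must be the anchor"),
        ],
    )
    def test_each_invariant_violation_rejected(self, mutation, message):
        part = _partition(**mutation)
        with pytest.raises(ValidationError, match=message):
            part.validate(7)

    def test_out_of_range_index(self, tmp_path):
        part = _partition()
        write_partition(part, tmp_path / "p.tsv")
        with pytest.raises(ValidationError, match="out of range"):
            read_partition(tmp_path / "p.tsv", _structure(5))

    def test_mapping_property(self):
        part = _partition()
        assert part.mapping == {1: 4, 2: 5}


class TestSchedule:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("lam\tlam1\tlam2\talpha\tu0\n0\t0\t0\t0.1\t110\n1\t1\t1\t0.1\t110\n")
        states = read_schedule(p)
        assert len(states) == 2
        assert states[0].lam == 0 and states[1].lam == 1

    def test_unsorted_rows_returned_sorted(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "lam\tlam1\tlam2\talpha\tu0\n0.5\t0\t1\t0.1\t110\n0\t0\t0\t0.1\t110\n"
        )
        states = read_schedule(p)
        assert [s.lam for s in states] == [0.0, 0.5]

    def test_out_of_range_lam_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("lam\tlam1\tlam2\talpha\tu0\n1.5\t0\t0\t0.1\t110\n")
        with pytest.raises(ValidationError):
            read_schedule(p)

    def test_duplicate_lam_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "lam\tlam1\tlam2\talpha\tu0\n0.5\t0\t1\t0.1\t110\n0.5\t0\t1\t0.1\t110\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_schedule(p)

    def test_shipped_default_schedule_has_22_states(self):
        import atswap

        states = read_schedule(atswap.packaged_data("schedule_22.tsv"))
        assert len(states) == 22

    def test_schedule_round_trip(self, tmp_path):
        from atswap.alchemy import default_schedule

        states = default_schedule(n_states=5)
        write_schedule(states, tmp_path / "s.tsv")
        assert read_schedule(tmp_path / "s.tsv") == states


def _sampleset():
    states = [
        LambdaState(0.0, 0.0, 0.0, 0.1, 110.0),
        LambdaState(1.0, 1.0, 1.0, 0.1, 110.0),
    ]
    rng = np.random.default_rng(0)
    u = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
    return SampleSet(
        states=states,
        temperature=300.0,
        softcore=SoftcoreParams(),
        sweeps=[np.arange(10), np.arange(10)],
        u_sc=u,
        u0=[np.zeros(10), np.zeros(10)],
        equil_fraction=0.5,
    )


class TestSamples:
    def test_round_trip_identity(self, tmp_path):
        ss = _sampleset()
        write_samples(ss, tmp_path / "s.tsv")
        ss2 = read_samples(tmp_path / "s.tsv")
        assert ss2.states == ss.states
        assert ss2.temperature == ss.temperature
        assert ss2.equil_fraction == ss.equil_fraction
        for k in range(2):
            assert np.array_equal(ss2.u_sc[k], ss.u_sc[k])
            assert np.array_equal(ss2.sweeps[k], ss.sweeps[k])

    def test_u_sc_above_umax_rejected(self, tmp_path):
        ss = _sampleset()
        write_samples(ss, tmp_path / "s.tsv")
        text = (tmp_path / "s.tsv").read_text()
        text += "1\t99\t250.0\t0.0\n"
        (tmp_path / "s.tsv").write_text(text)
        with pytest.raises(ValidationError, match="u_max"):
            read_samples(tmp_path / "s.tsv")

    def test_empty_state_block_allowed(self, tmp_path):
        ss = _sampleset()
        ss.u_sc[1] = np.empty(0)
        ss.sweeps[1] = np.empty(0, dtype=int)
        ss.u0[1] = np.empty(0)
        write_samples(ss, tmp_path / "s.tsv")
        ss2 = read_samples(tmp_path / "s.tsv")
        assert ss2.n_states == 2
        assert ss2.u_sc[1].size == 0

    def test_missing_metadata_is_error(self, tmp_path):
        (tmp_path / "s.tsv").write_text("state\tsweep\tu_sc\tU0\n0\t0\t0.0\t0.0\n")
        with pytest.raises(FormatError, match="metadata"):
            read_samples(tmp_path / "s.tsv")


class TestNetworkType:
    def test_rejects_self_edge_and_duplicates(self):
        net = FreeEnergyNetwork()
        net.add_edge("A", "B", 1.0, 0.1)
        with pytest.raises(ValidationError):
            net.add_edge("A", "A", 0.0)
        with pytest.raises(ValidationError):
            net.add_edge("A", "B", 2.0)

    def test_label_normalization(self):
        net = FreeEnergyNetwork()
        net.add_edge("A0 V", "WT", -2.63, 0.2)
        assert net.ddg("A0V", "WT") == -2.63


class TestStructureInvariants:
    def test_noncontiguous_indices_rejected(self):
        atoms = [Atom(0, "C", "C"), Atom(2, "C", "C")]
        with pytest.raises(ValidationError, match="contiguous"):
            Structure(atoms=atoms, coords=np.zeros((2, 3)))

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValidationError):
            Structure(atoms=[Atom(0, "C", "C")], coords=np.array([[np.inf, 0, 0]]))
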