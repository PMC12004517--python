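"""Readers and writers for structures, partitions, schedules, samples
and free-energy edge lists.

Structures travel as plain PDB (ATOM/HETATM records only, parsed with
biotite); everything else is tab-separated text so that runs remain
inspectable and diffable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import numpy as np
import pandas as pd

from .model import (
    AlchemicalPartition,
    Atom,
    FormatError,
    FreeEnergyNetwork,
    LambdaState,
    SampleSet,
    SoftcoreParams,
    Structure,
    ValidationError,
    infer_element,
)

_PDB_RECORDS = ("ATOM", "HETATM")


def _check_pdb_lines(lines: list[str], path: str) -> int:
    """Pre-validate ATOM/HETATM records so a malformed line is reported
    by number instead of surfacing as an opaque parse failure."""
    n = 0
    for i, line in enumerate(lines, start=1):
        if not line.startswith(_PDB_RECORDS):
            continue
        n += 1
        if len(line.rstrip("\n")) < 54:
            raise FormatError(f"{path}, line {i}: truncated ATOM record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise FormatError(
                    f"{path}, line {i}: unparseable {what} coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None
    return n


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a Structure (0-based atom indices, Å)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n_records = _check_pdb_lines(lines, str(path))
    if n_records == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    pdb_file = _pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        if not element:
            element = infer_element(str(arr.atom_name[i]))
        atoms.append(
            Atom(
                index=i,
                name=str(arr.atom_name[i]),
                element=element,
                res_id=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
            )
        )
    return Structure(atoms=atoms, coords=np.array(arr.coord, dtype=float))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width ATOM records (3-decimal coords)."""
    coords = structure.coords
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinate")
    if np.any(np.abs(coords) >= 10000.0):
        raise ValidationError(
            "coordinate magnitude >= 10000 Å overflows the PDB column width"
        )
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.array([a.name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element for a in structure.atoms], dtype="U2")
    arr.res_id = np.array([a.res_id for a in structure.atoms], dtype=int)
    arr.chain_id = np.array([a.chain for a in structure.atoms], dtype="U4")
    arr.res_name = np.array(["UNK"] * n, dtype="U5")
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


_PARTITION_ROLES = (
    "receptor",
    "commonA",
    "commonB",
    "variableA",
    "variableB",
    "solvent",
    "anchorA",
    "anchorB",
    "frameA",
    "frameB",
)


def read_partition(path: str | Path, structure: Structure) -> AlchemicalPartition:
    """Read the partition TSV (columns ``role``, ``atom_index``; row
    order of commonA/commonB defines the core mapping) and validate it
    against ``structure``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("role", "atom_index"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    by_role: dict[str, list[int]] = {r: [] for r in _PARTITION_ROLES}
    for _, row in df.iterrows():
        role = str(row["role"])
        if role not in by_role:
            raise FormatError(f"{path}: unknown role {role!r}")
        idx = int(row["atom_index"])
        if not 0 <= idx < structure.n_atoms:
            raise ValidationError(
                f"atom index {idx} out of range for a {structure.n_atoms}-atom structure"
            )
        by_role[role].append(idx)
    for role in ("anchorA", "anchorB"):
        if len(by_role[role]) != 1:
            raise ValidationError(f"exactly one {role} row required")
    # anchors belong to the common regions; anchor rows only mark them
    frame_a = tuple(by_role["frameA"]) if by_role["frameA"] else None
    frame_b = tuple(by_role["frameB"]) if by_role["frameB"] else None
    part = AlchemicalPartition(
        receptor=frozenset(by_role["receptor"]),
        common_a=by_role["commonA"],
        common_b=by_role["commonB"],
        variable_a=frozenset(by_role["variableA"]),
        variable_b=frozenset(by_role["variableB"]),
        solvent=frozenset(by_role["solvent"]),
        anchor_a=by_role["anchorA"][0],
        anchor_b=by_role["anchorB"][0],
        frame_a=frame_a,  # type: ignore[arg-type]
        frame_b=frame_b,  # type: ignore[arg-type]
    )
    part.validate(structure.n_atoms)
    return part


def write_partition(partition: AlchemicalPartition, path: str | Path) -> None:
    rows = [("receptor", i) for i in sorted(partition.receptor)]
    rows += [("commonA", i) for i in partition.common_a]
    rows += [("commonB", i) for i in partition.common_b]
    rows += [("variableA", i) for i in sorted(partition.variable_a)]
    rows += [("variableB", i) for i in sorted(partition.variable_b)]
    rows += [("solvent", i) for i in sorted(partition.solvent)]
    rows += [("anchorA", partition.anchor_a), ("anchorB", partition.anchor_b)]
    if partition.frame_a:
        rows += [("frameA", i) for i in partition.frame_a]
    if partition.frame_b:
        rows += [("frameB", i) for i in partition.frame_b]
    pd.DataFrame(rows, columns=["role", "atom_index"]).to_csv(
        path, sep="\t", index=False
    )


_SCHEDULE_COLS = ("lam", "lam1", "lam2", "alpha", "u0")


def read_schedule(path: str | Path) -> list[LambdaState]:
    """Read a λ-schedule TSV; rows are returned sorted by λ ascending."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _SCHEDULE_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    lams = df["lam"].to_numpy(dtype=float)
    if np.any((lams < 0) | (lams > 1)):
        raise ValidationError("lam outside [0,1]")
    if len(np.unique(lams)) != len(lams):
        raise ValidationError("duplicate lam values in schedule")
    df = df.sort_values("lam")
    return [
        LambdaState(
            lam=float(r.lam),
            lam1=float(r.lam1),
            lam2=float(r.lam2),
            alpha=float(r.alpha),
            u0=float(r.u0),
        )
        for r in df.itertuples()
    ]


def write_schedule(states: list[LambdaState], path: str | Path) -> None:
    pd.DataFrame(
        [(s.lam, s.lam1, s.lam2, s.alpha, s.u0) for s in states],
        columns=list(_SCHEDULE_COLS),
    ).to_csv(path, sep="\t", index=False)


def write_samples(samples: SampleSet, path: str | Path) -> None:
    """Write a SampleSet in the sample TSV dialect: ``#`` metadata header
    lines followed by columns ``state sweep u_sc U0``."""
    buf = _io.StringIO()
    buf.write(f"# temperature\t{samples.temperature!r}\n")
    sc = samples.softcore
    buf.write(f"# softcore\t{sc.u_max!r}\t{sc.u_c!r}\t{sc.a!r}\n")
    buf.write(f"# equil_fraction\t{samples.equil_fraction!r}\n")
    for k, s in enumerate(samples.states):
        buf.write(
            f"# state\t{k}\t{s.lam!r}\t{s.lam1!r}\t{s.lam2!r}\t{s.alpha!r}\t{s.u0!r}\n"
        )
    buf.write("state\tsweep\tu_sc\tU0\n")
    for k in range(samples.n_states):
        for sweep, usc, u0 in zip(samples.sweeps[k], samples.u_sc[k], samples.u0[k]):
            buf.write(f"{k}\t{int(sweep)}\t{float(usc)!r}\t{float(u0)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_samples(path: str | Path) -> SampleSet:
    path = Path(path)
    temperature = None
    softcore = None
    equil_fraction = 0.0
    states: dict[int, LambdaState] = {}
    body_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            key = fields[0]
            if key == "temperature":
                temperature = float(fields[1])
            elif key == "softcore":
                softcore = SoftcoreParams(
                    u_max=float(fields[1]), u_c=float(fields[2]), a=float(fields[3])
                )
            elif key == "equil_fraction":
                equil_fraction = float(fields[1])
            elif key == "state":
                states[int(fields[1])] = LambdaState(
                    lam=float(fields[2]),
                    lam1=float(fields[3]),
                    lam2=float(fields[4]),
                    alpha=float(fields[5]),
                    u0=float(fields[6]),
                )
            else:
                raise FormatError(f"{path}: unknown metadata key {key!r}")
        elif line.strip():
            body_lines.append(line)
    if temperature is None or softcore is None or not states:
        raise FormatError(f"{path}: incomplete metadata header")
    if sorted(states) != list(range(len(states))):
        raise FormatError(f"{path}: state metadata indices not contiguous")
    df = pd.read_csv(
        _io.StringIO("\n".join(body_lines)), sep="\t", float_precision="round_trip"
    )
    for col in ("state", "sweep", "u_sc", "U0"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) and (df["state"].min() < 0 or df["state"].max() >= len(states)):
        raise FormatError(f"{path}: sample references an undeclared state")
    sweeps, u_sc, u0 = [], [], []
    for k in range(len(states)):
        block = df[df["state"] == k]
        sweeps.append(block["sweep"].to_numpy(dtype=int))
        u_sc.append(block["u_sc"].to_numpy(dtype=float))
        u0.append(block["U0"].to_numpy(dtype=float))
    return SampleSet(
        states=[states[k] for k in range(len(states))],
        temperature=temperature,
        softcore=softcore,
        sweeps=sweeps,
        u_sc=u_sc,
        u0=u0,
        equil_fraction=equil_fraction,
    )


def read_network(path: str | Path) -> FreeEnergyNetwork:
    """Read a directed edge list TSV with columns ``from to ddG sigma``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("from", "to", "ddG"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    net = FreeEnergyNetwork()
    for _, row in df.iterrows():
        sigma = float(row["sigma"]) if "sigma" in df.columns else 0.0
        net.add_edge(str(row["from"]), str(row["to"]), float(row["ddG"]), sigma)
    return net


def write_network(net: FreeEnergyNetwork, path: str | Path) -> None:
    rows = [(a, b, ddg, sig) for (a, b), (ddg, sig) in net.edges.items()]
    pd.DataFrame(rows, columns=["from", "to", "ddG", "sigma"]).to_csv(
        path, sep="\t", index=False
    )
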