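"""Metropolis sampling of the λ-coupled potential and synchronous
Hamiltonian replica exchange over a λ schedule.

The sampler draws from exp(−β[U0(x) + W_λ(u_sc(x)) + R(x)]) with
single-atom Gaussian displacement proposals; R collects the restraint
terms, which bias both physical end states identically and therefore
cancel from the free-energy differences.  Replica exchange is
synchronous nearest-neighbor with alternating even/odd pairing — the
estimators consume equilibrium samples, so the exchange schedule only
affects mixing, not the estimated free energies.  Everything is a pure
function of the run seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import alchemy, transform
from .model import (
    AlchemicalPartition,
    LambdaState,
    SampleSet,
    SoftcoreParams,
    Structure,
    ValidationError,
    beta as inv_temperature,
)
from .restraints import RestraintSet, restraint_energy
from .toyff import EnergyModel


@dataclass
class System:
    """A sampleable system: structure + partition + energy model +
    restraints, with the alchemical mode fixed at construction."""

    structure: Structure
    partition: AlchemicalPartition
    model: EnergyModel
    restraints: RestraintSet | None = None
    mode: str = "ats"
    displacement: transform.Displacement | None = None
    temperature: float = 300.0
    softcore: SoftcoreParams = SoftcoreParams()
    frozen: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.partition.validate(self.structure.n_atoms)
        if self.mode not in ("ats", "atm"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "atm" and self.displacement is None:
            raise ValidationError("mode='atm' requires a displacement")
        self.frozen = frozenset(self.frozen)

    @property
    def movable(self) -> list[int]:
        return [i for i in range(self.structure.n_atoms) if i not in self.frozen]

    def perturbation(self, coords: np.ndarray) -> float:
        return transform.perturbation_energy(
            coords, self.partition, self.model, mode=self.mode, d=self.displacement
        )

    def evaluate(self, coords: np.ndarray) -> tuple[float, float, float]:
        """(U0 physical, restraint energy, perturbation u) at coords."""
        u0 = self.model.total_energy(coords)
        rest = restraint_energy(coords, self.restraints, self.partition)
        u = self.perturbation(coords)
        return u0, rest, u


@dataclass
class ReplicaState:
    state_index: int
    coords: np.ndarray
    u_phys: float = math.nan
    u_rest: float = math.nan
    u: float = math.nan
    u_sc: float = math.nan
    move_sigma: dict[int, float] = field(default_factory=dict)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def refresh(self, system: System) -> None:
        self.u_phys, self.u_rest, self.u = system.evaluate(self.coords)
        self.u_sc = alchemy.softcore(self.u, system.softcore)


def _state_energy(replica: ReplicaState, state: LambdaState) -> float:
    return replica.u_phys + replica.u_rest + alchemy.softplus_w(replica.u_sc, state)


def metropolis_step(
    replica: ReplicaState,
    system: System,
    state: LambdaState,
    move_sigma: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, bool]:
    """One single-atom Gaussian displacement proposal; returns the moved
    atom and whether the proposal was accepted (cached energies are
    refreshed on acceptance).  Move sizes are kept per atom because the
    stiffness — and hence the useful step — can differ by orders of
    magnitude between restrained and free atoms."""
    rng = rng if rng is not None else replica.rng
    movable = system.movable
    atom = movable[int(rng.integers(len(movable)))]
    sigma = (
        move_sigma
        if move_sigma is not None
        else replica.move_sigma.get(atom, 0.3)
    )
    proposal = replica.coords.copy()
    proposal[atom] += rng.normal(0.0, sigma, size=3)
    try:
        u_phys, u_rest, u = system.evaluate(proposal)
    except ValidationError:
        return atom, False  # singular energy (e.g. exact LJ overlap): reject
    u_sc = alchemy.softcore(u, system.softcore)
    e_old = _state_energy(replica, state)
    e_new = u_phys + u_rest + alchemy.softplus_w(u_sc, state)
    d_e = e_new - e_old
    if math.isnan(d_e) or d_e == math.inf:
        return atom, False
    b = inv_temperature(system.temperature)
    if d_e <= 0.0 or rng.random() < math.exp(-b * d_e):
        replica.coords = proposal
        replica.u_phys, replica.u_rest, replica.u, replica.u_sc = (
            u_phys,
            u_rest,
            u,
            u_sc,
        )
        return atom, True
    return atom, False


def attempt_exchange(
    rep_i: ReplicaState,
    rep_j: ReplicaState,
    schedule: list[LambdaState],
    b: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis state swap between two replicas.

    Δ = [W_i(u_j) + W_j(u_i)] − [W_i(u_i) + W_j(u_j)]; the physical and
    restraint energies cancel because all replicas share them."""
    if rep_i is rep_j:
        return False
    si = schedule[rep_i.state_index]
    sj = schedule[rep_j.state_index]
    delta = (
        alchemy.softplus_w(rep_j.u_sc, si)
        + alchemy.softplus_w(rep_i.u_sc, sj)
        - alchemy.softplus_w(rep_i.u_sc, si)
        - alchemy.softplus_w(rep_j.u_sc, sj)
    )
    if delta <= 0.0 or rng.random() < math.exp(-b * delta):
        rep_i.state_index, rep_j.state_index = rep_j.state_index, rep_i.state_index
        return True
    return False


def anneal(
    system: System,
    coords: np.ndarray,
    n_sweeps: int = 250,
    lam_target: float = 0.5,
    seed: int = 0,
    alpha: float = 0.1,
    u0: float = 110.0,
    move_sigma: float = 0.3,
) -> tuple[np.ndarray, dict[int, float]]:
    """Slow annealing from λ=0 to the λ=lam_target intermediate: a
    linear λ ramp, one Metropolis pass per sweep.  Returns the final
    coordinates and the tuned per-atom move sizes, used to seed every
    replica of the subsequent exchange run."""
    rng = np.random.default_rng(seed)
    rep = ReplicaState(state_index=0, coords=np.asarray(coords, float).copy(), rng=rng)
    rep.move_sigma = {a: move_sigma for a in system.movable}
    rep.refresh(system)
    n_mov = len(system.movable)
    acc: dict[int, list[int]] = {a: [0, 0] for a in system.movable}
    for sweep in range(n_sweeps):
        lam = lam_target * (sweep + 1) / n_sweeps
        state = alchemy.lambda_params(lam, alpha, u0)
        for _ in range(n_mov):
            atom, ok = metropolis_step(rep, system, state)
            acc[atom][0] += ok
            acc[atom][1] += 1
        # aggressive early tuning: stiffness can differ by orders of
        # magnitude between atoms and the start value is a guess
        if (sweep + 1) % 10 == 0:
            _tune_sigmas(rep.move_sigma, acc, factor=1.5)
    return rep.coords, dict(rep.move_sigma)


def _tune_sigmas(
    sigmas: dict[int, float], acc: dict[int, list[int]], factor: float = 1.3
) -> None:
    """Nudge per-atom move sizes toward the 30-50% acceptance window."""
    for atom, (n_acc, n_att) in acc.items():
        if n_att == 0:
            continue
        rate = n_acc / n_att
        if rate > 0.5:
            sigmas[atom] = min(sigmas[atom] * factor, 10.0)
        elif rate < 0.3:
            sigmas[atom] = max(sigmas[atom] / factor, 1e-4)
        acc[atom][0] = acc[atom][1] = 0


def run_hrex(
    system: System,
    schedule: list[LambdaState],
    n_sweeps: int,
    steps_per_sweep: int | None = None,
    sample_interval: int = 1,
    equil_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    anneal_sweeps: int = 0,
    initial_move_sigma: float = 0.3,
    tune: bool = True,
    exchange_phases: int = 8,
    return_stats: bool = False,
):
    """Synchronous Hamiltonian replica exchange over the schedule.

    One sweep = one Metropolis pass per replica (``steps_per_sweep``
    proposals, default one per movable atom) followed by one exchange
    phase over alternating even/odd neighbor pairs.  Per-state u_sc
    series are recorded every ``sample_interval`` sweeps; the first
    ``equil_fraction`` of each state's samples is marked as
    equilibration (the sampleset carries the fraction; the estimators
    discard it).  Move sizes are tuned toward 30–50% acceptance during
    the equilibration phase only, then frozen.  Deterministic given the
    seed.
    """
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    if len(schedule) < 2:
        raise ValidationError("schedule needs at least 2 states")
    if not 0.0 <= equil_fraction < 1.0:
        raise ValidationError("equil_fraction must be in [0, 1)")
    k_states = len(schedule)
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(k_states + 2)
    exchange_rng = np.random.default_rng(children[k_states])

    coords0 = system.structure.coords.copy()
    sigma0 = {a: initial_move_sigma for a in system.movable}
    if anneal_sweeps > 0:
        coords0, sigma0 = anneal(
            system,
            coords0,
            n_sweeps=anneal_sweeps,
            seed=children[k_states + 1],
            alpha=schedule[0].alpha,
            u0=schedule[0].u0,
            move_sigma=initial_move_sigma,
        )

    replicas = []
    for k in range(k_states):
        rep = ReplicaState(
            state_index=k,
            coords=coords0.copy(),
            move_sigma=dict(sigma0),
            rng=np.random.default_rng(children[k]),
        )
        rep.refresh(system)
        replicas.append(rep)

    n_mov = len(system.movable)
    steps = steps_per_sweep if steps_per_sweep is not None else max(n_mov, 1)
    equil_sweeps = int(equil_fraction * n_sweeps)
    tune_interval = 10
    acc_counts = [
        {a: [0, 0] for a in system.movable} for _ in range(k_states)
    ]
    exch_att = np.zeros(k_states - 1, dtype=int)
    exch_acc = np.zeros(k_states - 1, dtype=int)

    rec_sweeps: list[list[int]] = [[] for _ in range(k_states)]
    rec_usc: list[list[float]] = [[] for _ in range(k_states)]
    rec_u0: list[list[float]] = [[] for _ in range(k_states)]

    b = inv_temperature(system.temperature)
    for sweep in range(n_sweeps):
        for r, rep in enumerate(replicas):
            state = schedule[rep.state_index]
            for _ in range(steps):
                atom, ok = metropolis_step(rep, system, state)
                acc_counts[r][atom][0] += ok
                acc_counts[r][atom][1] += 1
        if tune and sweep < equil_sweeps and (sweep + 1) % tune_interval == 0:
            fast = sweep < equil_sweeps // 2
            for r, rep in enumerate(replicas):
                _tune_sigmas(rep.move_sigma, acc_counts[r], factor=1.5 if fast else 1.3)
        # exchange phases: alternate even/odd nearest-neighbor pairs;
        # attempts are nearly free (no energy re-evaluation), so several
        # phases per sweep speed replica flow through the schedule
        for phase in range(exchange_phases):
            by_state = {rep.state_index: rep for rep in replicas}
            start = (sweep + phase) % 2
            for k in range(start, k_states - 1, 2):
                exch_att[k] += 1
                exch_acc[k] += attempt_exchange(
                    by_state[k], by_state[k + 1], schedule, b, exchange_rng
                )
        if (sweep + 1) % sample_interval == 0:
            for rep in replicas:
                k = rep.state_index
                rec_sweeps[k].append(sweep)
                rec_usc[k].append(rep.u_sc)
                rec_u0[k].append(rep.u_phys)

    samples = SampleSet(
        states=list(schedule),
        temperature=system.temperature,
        softcore=system.softcore,
        sweeps=[np.asarray(s, dtype=int) for s in rec_sweeps],
        u_sc=[np.asarray(u) for u in rec_usc],
        u0=[np.asarray(u) for u in rec_u0],
        equil_fraction=equil_fraction,
    )
    if return_stats:
        stats = {
            "exchange_attempts": exch_att.tolist(),
            "exchange_accepts": exch_acc.tolist(),
            "move_sigma": [dict(rep.move_sigma) for rep in replicas],
        }
        return samples, stats
    return samples
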