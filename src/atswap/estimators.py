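"""Free-energy estimation: one-sided exponential averaging, the
multistate UWHAM estimator (unbinned WHAM, equivalent to MBAR), a
two-state Bennett acceptance-ratio solver, and moving-block bootstrap
uncertainties.

Every state's reduced energy is a function of the recorded soft-core
perturbation energy alone — u_kn = β·W_k(u_sc,n) — because the physical
potential U0 is shared by all states and cancels from state differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

from .alchemy import softplus_w
from .model import KB, SampleSet, ValidationError, beta as inv_temperature


def exp_estimator(u_samples, temperature: float) -> float:
    """One-sided exponential-average free energy,
    −(1/β)·ln⟨exp(−βu)⟩, computed with a log-sum-exp guard."""
    u = np.asarray(u_samples, dtype=float)
    if u.size == 0:
        raise ValidationError("empty sample array")
    b = inv_temperature(temperature)
    return float(-(logsumexp(-b * u) - math.log(u.size)) / b)


def discard_equilibration(samples: SampleSet, fraction: float | None = None) -> SampleSet:
    """Drop the first ⌈fraction·n_k⌉ samples of each state (default: the
    fraction recorded on the sample set, else 1/3)."""
    if fraction is None:
        fraction = samples.equil_fraction if samples.equil_fraction > 0 else 1.0 / 3.0
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must be in [0, 1)")
    sweeps, u_sc, u0 = [], [], []
    for k in range(samples.n_states):
        n = samples.u_sc[k].size
        n_drop = math.ceil(fraction * n)
        if n > 0 and n_drop >= n:
            warnings.warn(f"state {k}: all {n} samples discarded as equilibration")
        sweeps.append(samples.sweeps[k][n_drop:])
        u_sc.append(samples.u_sc[k][n_drop:])
        u0.append(samples.u0[k][n_drop:])
    return SampleSet(
        states=samples.states,
        temperature=samples.temperature,
        softcore=samples.softcore,
        sweeps=sweeps,
        u_sc=u_sc,
        u0=u0,
        equil_fraction=0.0,
    )


def _reduced_potentials(samples: SampleSet, temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """(K×N reduced-energy matrix over pooled samples, per-state counts)."""
    b = inv_temperature(temperature)
    pooled = np.concatenate([u for u in samples.u_sc if u.size] or [np.empty(0)])
    counts = samples.counts
    u_kn = np.empty((samples.n_states, pooled.size))
    for k, state in enumerate(samples.states):
        u_kn[k] = b * softplus_w(pooled, state)
    return u_kn, counts


@dataclass
class UWHAMResult:
    free_energies: np.ndarray  # kcal/mol, pinned F_0 = 0
    ddg: float  # F_last − F_first, kcal/mol
    n_samples: np.ndarray
    n_iterations: int

    @property
    def f_k(self) -> np.ndarray:
        return self.free_energies


def _sc_iteration(f: np.ndarray, u_kn: np.ndarray, log_n: np.ndarray) -> np.ndarray:
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
    return f_new - f_new[0]


def uwham(
    samples: SampleSet,
    temperature: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100000,
    f_init: np.ndarray | None = None,
) -> UWHAMResult:
    """Self-consistent UWHAM solution over all states.

    Reduced energies are reconstructed per pooled sample for every state
    as β·W_k(u_sc).  The dimensionless free energies are first located by
    minimizing the (convex) UWHAM objective with L-BFGS, then polished by
    self-consistent iteration until max|ΔF| < tol kcal/mol.  F is pinned
    at F_0 = 0; ``ddg`` is the free energy of the last state relative to
    the first, which for an endpoint-to-endpoint schedule is the relative
    binding free energy.
    """
    temperature = temperature if temperature is not None else samples.temperature
    counts = samples.counts
    occupied = counts > 0
    if not occupied.all():
        raise ValidationError(
            "every state needs at least one production sample "
            f"(empty: {list(np.flatnonzero(~occupied))})"
        )
    if samples.n_states < 2:
        raise ValidationError("uwham needs >= 2 states with samples")
    u_kn, counts = _reduced_potentials(samples, temperature)
    k_states, n_tot = u_kn.shape
    log_n = np.log(counts.astype(float))
    kt = KB * temperature

    f = np.zeros(k_states) if f_init is None else np.asarray(f_init, float) / kt
    f = f - f[0]

    def objective(theta: np.ndarray):
        fk = np.concatenate([[0.0], theta])
        log_denom = logsumexp(log_n[:, None] + fk[:, None] - u_kn, axis=0)
        val = float(np.sum(log_denom) - np.dot(counts, fk))
        w = np.exp(log_n[:, None] + fk[:, None] - u_kn - log_denom[None, :])
        grad = w.sum(axis=1) - counts
        return val, grad[1:]

    res = minimize(objective, f[1:], jac=True, method="L-BFGS-B")
    f = np.concatenate([[0.0], res.x])

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        f_new = _sc_iteration(f, u_kn, log_n)
        delta = float(np.max(np.abs(f_new - f))) * kt
        f = f_new
        if delta < tol:
            break
    else:
        raise ValidationError(
            f"UWHAM did not converge below {tol} kcal/mol in {max_iter} "
            "iterations (degenerate or non-overlapping states?)"
        )
    free = f * kt
    return UWHAMResult(
        free_energies=free,
        ddg=float(free[-1] - free[0]),
        n_samples=counts,
        n_iterations=n_iter,
    )


def bar(
    w_forward,
    w_reverse,
    temperature: float,
    tol: float = 1e-12,
) -> float:
    """Bennett acceptance ratio ΔF (kcal/mol) from forward work values
    (u1−u0 sampled in state 0) and reverse work values (u0−u1 sampled in
    state 1).  Solved as a root of the implicit BAR equation with Brent
    bracketing; kept independent of the UWHAM path so the two can serve
    as mutual cross-checks."""
    wf = np.asarray(w_forward, dtype=float)
    wr = np.asarray(w_reverse, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ValidationError("BAR needs samples in both states")
    b = inv_temperature(temperature)
    m_log = math.log(wf.size / wr.size)

    def implicit(df: float) -> float:
        # Bennett self-consistency: sum of Fermi weights of the forward
        # works equals that of the reverse works at the true ΔF
        lhs = logsumexp(-np.logaddexp(0.0, m_log + b * (wf - df)))
        rhs = logsumexp(-np.logaddexp(0.0, -m_log + b * (wr + df)))
        return lhs - rhs

    scale = float(np.max(np.abs(np.concatenate([wf, wr])))) + 10.0
    lo, hi = -scale, scale
    while implicit(lo) * implicit(hi) > 0:
        lo, hi = 2 * lo, 2 * hi
        if hi > 1e8:
            raise ValidationError("BAR equation could not be bracketed")
    return float(brentq(implicit, lo, hi, xtol=tol))


def integrated_autocorr_time(x, c: float = 5.0) -> float:
    """Integrated autocorrelation time τ = 1 + 2·Σρ_t with a
    self-consistent (Sokal) window: the sum is truncated at the first
    lag M ≥ c·τ(M).  The windowed form picks up small slowly-decaying
    tails that a truncate-at-first-negative rule would discard."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 1.0
    xc = x - x.mean()
    var = float(np.dot(xc, xc))
    if var == 0.0:
        return 1.0
    acov = np.correlate(xc, xc, mode="full")[n - 1 :]
    rho = acov / var
    taus = 2.0 * np.cumsum(rho) - 1.0
    for m in range(min(n // 2, taus.size)):
        if m >= c * taus[m]:
            return float(max(taus[m], 1.0))
    return float(max(taus[min(n // 2, taus.size) - 1], 1.0))


def _moving_block_resample(
    x: np.ndarray, block_len: int, rng: np.random.Generator
) -> np.ndarray:
    n = x.size
    if block_len > n:
        raise ValidationError(f"block_len {block_len} exceeds series length {n}")
    if n == 0:
        return x
    n_blocks = math.ceil(n / block_len)
    starts = rng.integers(0, n - block_len + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:n]
    return x[idx]


def bootstrap_sigma(
    samples: SampleSet,
    estimator,
    n_boot: int = 100,
    block_len: int | None = None,
    seed: int = 0,
) -> float:
    """Moving-block bootstrap standard deviation of ``estimator`` (a
    callable SampleSet → float).  Blocks are resampled within each state;
    the default block length is the largest per-state integrated
    autocorrelation time, rounded up.  Deterministic given the seed."""
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    lengths_present = [u.size for u in samples.u_sc if u.size]
    if block_len is not None and lengths_present and block_len > min(lengths_present):
        raise ValidationError(
            f"block_len {block_len} exceeds the shortest series "
            f"({min(lengths_present)})"
        )
    if block_len is None:
        taus = [
            integrated_autocorr_time(u) for u in samples.u_sc if u.size >= 4
        ]
        # replica-exchange output can carry memory that is invisible in
        # any single state's series but shows in time-aligned aggregates
        # (the whole replica pool relaxes jointly); include them when
        # the series are aligned
        sizes = {int(u.size) for u in samples.u_sc}
        if len(sizes) == 1 and sizes != {0} and samples.n_states > 1:
            stacked = np.vstack(samples.u_sc)
            taus.append(integrated_autocorr_time(stacked.mean(axis=0)))
            taus.append(integrated_autocorr_time(stacked[0] - stacked[-1]))
        # blocks of a few autocorrelation times keep the bias of the
        # moving-block variance estimate small
        block_len = max(1, math.ceil(4.0 * max(taus))) if taus else 1
        n_min = int(min(u.size for u in samples.u_sc))
        # keep at least ~10 blocks so the resample remains meaningful
        block_len = max(1, min(block_len, n_min // 10 if n_min >= 10 else n_min))
    rng = np.random.default_rng(seed)
    # Replica-exchange output is time-aligned across states (one sample
    # per state per sampling event) and the same configurations migrate
    # between states, so when the per-state series have equal lengths the
    # time blocks are resampled jointly — the same block indices for all
    # states — to preserve the cross-state covariance of the estimator.
    lengths = {int(u.size) for u in samples.u_sc}
    joint = len(lengths) == 1
    values = []
    for _ in range(n_boot):
        shared_order = None
        if joint:
            n = samples.u_sc[0].size
            if n:
                shared_order = _moving_block_resample(
                    np.arange(n), min(block_len, n), rng
                )
        u_sc, sweeps, u0 = [], [], []
        for k in range(samples.n_states):
            n = samples.u_sc[k].size
            if shared_order is not None:
                order = shared_order
            else:
                bl = min(block_len, n) if n else block_len
                order = (
                    _moving_block_resample(np.arange(n), bl, rng) if n else np.arange(0)
                )
            u_sc.append(samples.u_sc[k][order])
            sweeps.append(samples.sweeps[k][order])
            u0.append(samples.u0[k][order])
        resampled = SampleSet(
            states=samples.states,
            temperature=samples.temperature,
            softcore=samples.softcore,
            sweeps=sweeps,
            u_sc=u_sc,
            u0=u0,
            equil_fraction=0.0,
        )
        values.append(float(estimator(resampled)))
    return float(np.std(values, ddof=1))
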