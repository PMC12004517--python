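"""Soft-core perturbation energy, softplus coupling, and the
λ-interpolated alchemical potential.

The alchemical potential at state s is

    U_λ(x) = U0(x) + W_s(u_sc(x)),

where u = U1(x) − U0(x) is the perturbation energy for carrying the
system from the A-bound to the B-bound leg, u_sc caps u smoothly at
u_max above a threshold u_c, and the softplus coupling W_s interpolates
between slope λ1 (low energies) and λ2 (high energies):

    W(u) = (λ2 − λ1)/α · ln(1 + exp(−α(u − u0))) + λ2·u .

At the initial endpoint λ1 = λ2 = 0 so U_λ = U0; at the final endpoint
λ1 = λ2 = 1 so U_λ = U0 + u_sc, which equals U1 whenever u ≤ u_c.
"""

from __future__ import annotations

import math

import numpy as np

from .model import LambdaState, SoftcoreParams, ValidationError


def softcore(u, params: SoftcoreParams = SoftcoreParams()):
    """Soft-core cap of the raw perturbation energy.

    Identity for u ≤ u_c; above u_c increases monotonically and
    approaches u_max asymptotically, with a continuous first derivative
    (slope 1) at u_c.  Accepts scalars or arrays.
    """
    u_arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_arr)):
        raise ValidationError("non-finite perturbation energy")
    span = params.u_max - params.u_c
    y = np.maximum(u_arr - params.u_c, 0.0) / span
    ya = y / params.a
    z = 1.0 + 2.0 * ya + 2.0 * ya**2
    fsc = (z**params.a - 1.0) / (z**params.a + 1.0)
    out = np.where(u_arr <= params.u_c, u_arr, params.u_c + span * fsc)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(out)
    return out


def softplus_w(u_sc, state: LambdaState):
    """Softplus alchemical coupling W_λ(u_sc), kcal/mol.

    Monotone nondecreasing for λ2 ≥ λ1 ≥ 0, with slope λ1 as
    u_sc → −∞ and λ2 as u_sc → +∞; reduces exactly to λ·u_sc when
    λ1 = λ2 = λ.  Accepts scalars or arrays.
    """
    u_arr = np.asarray(u_sc, dtype=float)
    dlam = state.lam2 - state.lam1
    if dlam == 0.0:
        out = state.lam2 * u_arr
    else:
        if state.alpha == 0.0:
            raise ValidationError("alpha = 0 is degenerate when lam1 != lam2")
        # log(1 + e^{-α(u-u0)}) evaluated stably in both tails
        log_term = np.logaddexp(0.0, -state.alpha * (u_arr - state.u0))
        out = dlam / state.alpha * log_term + state.lam2 * u_arr
    if np.isscalar(u_sc) or u_arr.ndim == 0:
        return float(out)
    return out


def softplus_slope(u_sc, state: LambdaState):
    """Analytic dW/du_sc (used by slope-contract tests)."""
    u_arr = np.asarray(u_sc, dtype=float)
    dlam = state.lam2 - state.lam1
    if dlam == 0.0:
        out = np.full_like(u_arr, state.lam2)
    else:
        z = state.alpha * (u_arr - state.u0)
        # λ2 − (λ2−λ1)·sigmoid(−z): slope λ1 in the low-u tail, λ2 high
        out = state.lam2 - dlam * _sigmoid(-z)
    if np.isscalar(u_sc) or u_arr.ndim == 0:
        return float(out)
    return out


def _sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def alchemical_potential(
    u0: float, u: float, state: LambdaState, params: SoftcoreParams = SoftcoreParams()
) -> float:
    """U_λ = U0 + W_λ(u_sc(u)), kcal/mol."""
    if not (math.isfinite(u0) and math.isfinite(u)):
        raise ValidationError("non-finite energy input")
    return u0 + softplus_w(softcore(u, params), state)


def lambda_params(
    lam: float, alpha: float = 0.1, u0: float = 110.0
) -> LambdaState:
    """The shipped λ → (λ1, λ2, α, u0) convention.

    Two linear legs: λ2 = min(1, 2λ) ramps over the first half of the
    path while λ1 stays 0, then λ1 = max(0, 2λ − 1) ramps over the
    second half.  The softplus crossover is active in the mid-window
    where λ1 ≠ λ2; the endpoints are exactly linear (λ1 = λ2 ∈ {0, 1}).
    """
    return LambdaState(
        lam=lam,
        lam1=max(0.0, 2.0 * lam - 1.0),
        lam2=min(1.0, 2.0 * lam),
        alpha=alpha,
        u0=u0,
    )


def default_schedule(
    n_states: int = 22, alpha: float = 0.1, u0: float = 110.0
) -> list[LambdaState]:
    """The default 22-state schedule: λ_k = k/(n−1), mirror-symmetric
    about λ = 1/2 (states k and n−1−k have λ summing to 1), endpoints
    exactly linear with λ1 = λ2 = 0 and 1."""
    if n_states < 2:
        raise ValidationError("schedule needs at least 2 states")
    return [lambda_params(k / (n_states - 1), alpha, u0) for k in range(n_states)]
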