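"""Deterministic two-type Lotka-Volterra competition dynamics.

The model couples two logistic populations through dimensionless competition
coefficients::

    dn_r/dt = r_r * n_r * (1 - (n_r + alpha * n_K) / K_r)
    dn_K/dt = r_K * n_K * (1 - (n_K + beta  * n_r) / K_K)

``alpha`` weighs how strongly K cells crowd r cells and ``beta`` the reverse.
With ``alpha = beta = 0`` the system decouples into two independent logistic
curves, which serves as the analytic oracle for the integrator.

Long-run outcomes follow standard invasion analysis: r cells can invade the
K-only equilibrium iff ``alpha < K_r / K_K`` and K cells can invade the r-only
equilibrium iff ``beta < K_K / K_r``; both criteria holding means coexistence,
neither means founder control (bistability), exactly one means competitive
exclusion of the non-invader.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .errors import IntegrationError, InvalidInputError
from .params import InteractionParams, PhenotypeParams, PopulationState, Trajectory

__all__ = [
    "lv_rates",
    "logistic_closed_form",
    "integrate_lv",
    "classify_outcome",
    "DEFAULT_STEP_H",
]

#: Default fixed RK4 step (hours).  Fixed-step integration keeps trajectories
#: bit-reproducible across platforms for identical settings.
DEFAULT_STEP_H = 0.1


def lv_rates(
    state: PopulationState,
    pr: PhenotypeParams,
    pk: PhenotypeParams,
    inter: InteractionParams,
) -> tuple[float, float]:
    """Instantaneous net rates (dn_r/dt, dn_K/dt) in cells per hour.

    A phenotype with zero count has exactly zero rate (extinction is
    absorbing in the deterministic model).
    """
    if not (math.isfinite(state.n_r) and math.isfinite(state.n_K)):
        raise InvalidInputError("population counts must be finite")
    if state.n_r < 0 or state.n_K < 0:
        raise InvalidInputError("population counts must be non-negative")
    dn_r = pr.intrinsic_rate * state.n_r * (
        1.0 - (state.n_r + inter.alpha * state.n_K) / pr.carrying_capacity
    )
    dn_k = pk.intrinsic_rate * state.n_K * (
        1.0 - (state.n_K + inter.beta * state.n_r) / pk.carrying_capacity
    )
    return dn_r, dn_k


def logistic_closed_form(n0: float, r: float, K: float, t: float) -> float:
    """Analytic logistic solution ``n(t) = K / (1 + (K/n0 - 1) e^{-rt})``.

    Serves as the exact oracle for the decoupled (``alpha = beta = 0``) limit
    of the integrator.
    """
    if not (n0 > 0 and math.isfinite(n0)):
        raise InvalidInputError(f"n0 must be positive, got {n0}")
    if not (K > 0 and math.isfinite(K)):
        raise InvalidInputError(f"K must be positive, got {K}")
    return K / (1.0 + (K / n0 - 1.0) * math.exp(-r * t))


def _rhs(n: np.ndarray, rr: float, kr: float, rk: float, kk: float,
         alpha: float, beta: float) -> np.ndarray:
    nr, nk = n
    return np.array(
        [
            rr * nr * (1.0 - (nr + alpha * nk) / kr),
            rk * nk * (1.0 - (nk + beta * nr) / kk),
        ]
    )


def integrate_lv(
    state0: PopulationState,
    pr: PhenotypeParams,
    pk: PhenotypeParams,
    inter: InteractionParams,
    t_grid: Sequence[float],
    step: float = DEFAULT_STEP_H,
) -> Trajectory:
    """Integrate the competition ODE with classic fixed-step 4th-order RK.

    The trajectory is evaluated at every time in ``t_grid`` (which must start
    at ``state0.time`` and increase strictly); each grid interval is covered
    by equal sub-steps no longer than ``step``.  Undershoots below zero are
    clamped to zero with a warning, since counts are physical.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise InvalidInputError("t_grid must be a non-empty 1-D sequence")
    if not math.isclose(t_grid[0], state0.time, abs_tol=1e-12):
        raise InvalidInputError(
            f"t_grid must start at state0.time={state0.time}, got {t_grid[0]}"
        )
    if np.any(np.diff(t_grid) <= 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    if not (step > 0):
        raise InvalidInputError(f"step must be positive, got {step}")

    rr, kr = pr.intrinsic_rate, pr.carrying_capacity
    rk, kk = pk.intrinsic_rate, pk.carrying_capacity
    a, b = inter.alpha, inter.beta

    n = np.array([state0.n_r, state0.n_K], dtype=float)
    states = [PopulationState(n[0], n[1], float(t_grid[0]))]
    clamped = False
    for t1, t2 in zip(t_grid[:-1], t_grid[1:]):
        span = float(t2 - t1)
        n_sub = max(1, math.ceil(span / step - 1e-12))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = _rhs(n, rr, kr, rk, kk, a, b)
            k2 = _rhs(n + 0.5 * h * k1, rr, kr, rk, kk, a, b)
            k3 = _rhs(n + 0.5 * h * k2, rr, kr, rk, kk, a, b)
            k4 = _rhs(n + h * k3, rr, kr, rk, kk, a, b)
            n = n + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(n)):
                raise IntegrationError(
                    f"non-finite state at t~{t1:.6g}..{t2:.6g} h with step {h:.6g} h; "
                    "reduce the integration step"
                )
            if np.any(n < 0):
                clamped = True
                n = np.maximum(n, 0.0)
        states.append(PopulationState(float(n[0]), float(n[1]), float(t2)))
    if clamped:
        warnings.warn(
            "integration undershot zero; counts clamped at 0", RuntimeWarning, stacklevel=2
        )
    return Trajectory(
        states,
        metadata={
            "integrator": "rk4-fixed",
            "step_h": step,
            "pr": pr,
            "pk": pk,
            "inter": inter,
        },
    )


def classify_outcome(
    pr: PhenotypeParams, pk: PhenotypeParams, inter: InteractionParams
) -> str:
    """Long-run outcome by invasion analysis.

    Returns one of ``"r_excluded"``, ``"K_excluded"``, ``"coexistence"``,
    ``"bistable"``.  Boundary cases (an invasion criterion holding with
    equality) are classified as non-invading, i.e. the degenerate neutral
    direction is lumped with the closed one.
    """
    ratio = pr.carrying_capacity / pk.carrying_capacity
    r_invades = inter.alpha < ratio
    k_invades = inter.beta < 1.0 / ratio
    if r_invades and k_invades:
        return "coexistence"
    if r_invades:
        return "K_excluded"
    if k_invades:
        return "r_excluded"
    return "bistable"
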