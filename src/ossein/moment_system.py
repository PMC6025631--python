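"""Coupled regulator–moment ODE system and the compartment baseline.

This is the level actually integrated for whole-tissue trajectories.  The
age-structured collagen solution enters only through three scalar signals
— immature pool ``C1(t)``, mature pool ``C2(t)`` and maturity fraction
``F(t)`` — which drive five ODEs:

    I'  = 0.1 C1 - 0.2 C2 I                     (inhibitors, e.g. OPN/OC)
    N'  = 0.1 C1 - 0.012 N^2 / (0.001 + I^10)   (nucleators, e.g. BSP)
    wp' = (-0.1 C1 C2 - 0.1 C1^2) / (0.71 C2^2) (plastic energy)
    M'  = -k(N,I,F) M^2 + V(F) m(t,0)           (crystal count)
    P'  = V(F) M                                (mineral mass)

with ``m(t,0)`` the precipitation boundary density.  The ``wp`` equation
is the exact time derivative of the empirical crosslink-ratio law
``C1/C2 = 0.71 wp + 1`` when ``C1, C2`` follow the two-compartment
maturation ``C1' = -0.1 C1``, ``C2' = 0.1 C1``; ``wp`` is non-increasing
for any non-negative collagen trajectory.  The ``M, P`` equations are the
moment reduction of the size-structured crystal equation and must agree
with the structured solver under refinement.

The classical five-variable compartment model (immature/mature matrix
``x1, x2``, regulators ``I, N``, mineral density ``y``) is kept as
:func:`komarova_baseline` for comparison runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .collagen_age import AgeDensity, collagen_pools, maturity_series
from .kinetics import (
    KineticParameters,
    aggregation_rate,
    growth_velocity,
    precipitation_density,
    _hill_power,
)

__all__ = [
    "RegulatorState",
    "MomentState",
    "KomarovaParameters",
    "coupled_rhs",
    "simulate",
    "komarova_baseline",
    "ratio_energy",
    "ratio_to_energy",
    "consistent_wp0",
]

#: Transfer / decay rate constants of the regulator block, fixed to the
#: published calibration of the compartment model.
RATE_C1_TO_I = 0.1
RATE_I_DECAY = 0.2
RATE_C1_TO_N = 0.1
RATE_N_LOSS = 0.012
RATIO_SLOPE = 0.71


@dataclass
class RegulatorState:
    """Inhibitor and nucleator levels (dimensionless, non-negative)."""

    I: float = 0.55
    N: float = 0.7

    def __post_init__(self) -> None:
        if self.I < 0 or self.N < 0:
            raise ValueError("regulator levels must be non-negative")


@dataclass
class MomentState:
    """Crystal count ``M``, mineral mass ``P`` and plastic energy ``wp``."""

    M: float = 0.0
    P: float = 0.0
    wp: float = 1.0

    def __post_init__(self) -> None:
        if self.M < 0 or self.P < 0:
            raise ValueError("moments must be non-negative")
        if not np.isfinite(self.wp):
            raise ValueError("wp must be finite")


@dataclass(frozen=True)
class KomarovaParameters:
    """Rate constants of the compartment baseline model."""

    k1: float = 0.1
    v1: float = 0.1
    r1: float = 0.2
    k2: float = 1.0
    r2: float = 12.0
    k3: float = 1.0
    b: float = 1e-3
    a_hill: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k1", "v1", "r1", "k2", "r2", "k3", "b", "a_hill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def coupled_rhs(
    state,
    C1: float,
    C2: float,
    F: float,
    params: KineticParameters = KineticParameters(),
) -> np.ndarray:
    """Derivative of ``[I, N, wp, M, P]`` at given collagen signals.

    Raises
    ------
    ValueError
        If ``C2 = 0`` — the plastic-energy equation divides by ``C2^2``.
    """
    if C2 <= 0:
        raise ValueError("C2 must be positive: wp' divides by C2^2")
    I, N, wp, M, P = np.asarray(state, dtype=float)
    In = max(I, 0.0)
    Nn = max(N, 0.0)
    Mn = max(M, 0.0)
    dI = RATE_C1_TO_I * C1 - RATE_I_DECAY * C2 * I
    dN = RATE_C1_TO_N * C1 - RATE_N_LOSS * Nn**2 / (params.b + _hill_power(In, params.a_hill))
    dwp = (-0.1 * C1 * C2 - 0.1 * C1**2) / (RATIO_SLOPE * C2**2)
    k_val = aggregation_rate(Nn, In, min(max(F, 0.0), 1.0), params)
    V_val = growth_velocity(min(max(F, 0.0), 1.0), params)
    dM = -k_val * Mn**2 + V_val * precipitation_density(Nn, In, Mn, params)
    dP = V_val * Mn
    return np.array([dI, dN, dwp, dM, dP])


def consistent_wp0(c0: AgeDensity) -> float:
    """Plastic energy consistent with the crosslink-ratio law at ``t=0``.

    ``wp(0) = (C1(0)/C2(0) - 1) / 0.71``.  Negative for an initially
    mature matrix (ratio below 1), which the empirical law does not cover.
    """
    pools = collagen_pools(c0)
    return (pools.C1 / pools.C2 - 1.0) / RATIO_SLOPE


def simulate(
    c0: AgeDensity,
    regulators: RegulatorState = RegulatorState(),
    moments0: MomentState = MomentState(),
    params: KineticParameters = KineticParameters(),
    t_grid=None,
    wp_init: str = "printed",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the coupled system driven by the ageing collagen profile.

    The collagen transport equation is solved exactly (closed-form pools
    from :func:`~ossein.collagen_age.maturity_series`); the five ODEs are
    integrated adaptively on top of those signals.  The cascade is one-way:
    collagen -> regulators -> minerals, with no feedback.

    Parameters
    ----------
    c0
        Initial collagen age profile (its ``alpha`` is the maturity
        threshold; it should match ``params.alpha``).
    regulators, moments0
        Initial inhibitor/nucleator levels and mineral moments.  The
        plastic energy start honours the printed value ``wp(0)=1`` by
        default; ``wp_init="consistent"`` instead initialises it from the
        crosslink-ratio law (see :func:`consistent_wp0`).
    t_grid
        Increasing output times starting at 0 (default 201 points on
        ``[0, 2*alpha]``).

    Returns
    -------
    DataFrame with columns ``t, I, N, wp, M, P, F, C1, C2, mean_size``.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 2.0 * params.alpha, 201)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase from 0")
    if wp_init not in ("printed", "consistent"):
        raise ValueError("wp_init must be 'printed' or 'consistent'")

    pools = maturity_series(c0, t_grid)
    if np.any(pools["C2"].to_numpy() <= 0):
        raise ValueError("C2 must stay positive: wp' divides by C2^2")

    # dense collagen signals, exact at any t (piecewise-linear c0)
    from .collagen_age import _integral_below

    C = c0.total

    def signals(t: float) -> tuple[float, float, float]:
        C1 = _integral_below(c0.ages, c0.density, c0.alpha - t)
        C2 = C - C1
        return C1, C2, C2 / C

    wp0 = moments0.wp if wp_init == "printed" else consistent_wp0(c0)
    y0 = [regulators.I, regulators.N, wp0, moments0.M, moments0.P]

    if t_grid.size == 1:  # zero-length run: echo the initial state
        sol_y = np.array(y0, dtype=float).reshape(5, 1)
        return _assemble(t_grid, sol_y, pools)

    def rhs(t, y):
        C1, C2, F = signals(t)
        return coupled_rhs(y, C1, C2, F, params)

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else t_grid[0]
        raise RuntimeError(f"integration failed after t={last_t:g}: {sol.message}")

    return _assemble(t_grid, sol.y, pools)


def _assemble(t_grid: np.ndarray, y: np.ndarray, pools: pd.DataFrame) -> pd.DataFrame:
    I, N, wp, M, P = y
    out = pd.DataFrame(
        {
            "t": t_grid,
            "I": I,
            "N": N,
            "wp": wp,
            "M": M,
            "P": P,
            "F": pools["F"].to_numpy(),
            "C1": pools["C1"].to_numpy(),
            "C2": pools["C2"].to_numpy(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["mean_size"] = np.where(out["M"] > 0, out["P"] / out["M"], np.nan)
    return out


def komarova_baseline(
    x1_0: float = 1.0,
    x2_0: float = 0.0,
    I0: float = 0.55,
    N0: float = 0.7,
    y0: float = 0.0,
    params: KomarovaParameters = KomarovaParameters(),
    t_grid=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the five-variable compartment baseline model.

    ``x1' = -k1 x1``, ``x2' = k1 x1``, ``I' = v1 x1 - r1 x2 I``,
    ``N' = k2 x2' - r2 y' N``, ``y' = k3 b N / (b + I^a)``.

    Returns the trajectory together with the closed forms
    ``x1 = x1_0 e^{-k1 t}`` and ``x2 = x2_0 + x1_0 (1 - e^{-k1 t})``
    (columns ``x1_closed``, ``x2_closed``).
    """
    if min(x1_0, x2_0, I0, N0, y0) < 0:
        raise ValueError("initial state must be non-negative")
    if t_grid is None:
        t_grid = np.linspace(0.0, 50.0, 501)
    t_grid = np.asarray(t_grid, dtype=float)
    p = params

    def rhs(t, s):
        x1, x2, I, N, y = s
        dy = p.k3 * p.b * max(N, 0.0) / (p.b + _hill_power(max(I, 0.0), p.a_hill))
        return [
            -p.k1 * x1,
            p.k1 * x1,
            p.v1 * x1 - p.r1 * x2 * I,
            p.k2 * p.k1 * x1 - p.r2 * dy * N,
            dy,
        ]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [x1_0, x2_0, I0, N0, y0],
        t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    x1, x2, I, N, y = sol.y
    return pd.DataFrame(
        {
            "t": t_grid,
            "x1": x1,
            "x2": x2,
            "I": I,
            "N": N,
            "y": y,
            "x1_closed": x1_0 * np.exp(-p.k1 * t_grid),
            "x2_closed": x2_0 + x1_0 * (1.0 - np.exp(-p.k1 * t_grid)),
        }
    )


def ratio_energy(wp):
    """Immature/mature crosslink ratio from plastic energy: ``0.71 wp + 1``."""
    out = RATIO_SLOPE * np.asarray(wp, dtype=float) + 1.0
    return out if out.ndim else float(out)


def ratio_to_energy(ratio):
    """Inverse of :func:`ratio_energy`; requires ``ratio >= 1``."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 1.0):
        raise ValueError("ratio < 1 implies negative plastic energy")
    out = (ratio - 1.0) / RATIO_SLOPE
    return out if out.ndim else float(out)
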