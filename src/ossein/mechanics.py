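"""Macroscopic elasto-plastic mechanics layer.

Maps the microstructural state — collagen maturity fraction ``F`` and
crystal count ``M`` — onto a Ramberg–Osgood stress–strain law

    eps = sigma/E + beta * (sigma/E)**n

through three empirical polynomial maps:

    n(F, M)    = 30 F^10 - 0.1 M      (hardening exponent)
    beta(F, M) = -0.5 F^5 + 0.85 M    (plastic coefficient)
    E(F, M)    = -5 F^2 + 10 M        (elastic modulus, "coupled" mode)

A maturing, sparsely mineralized matrix raises ``n`` (later, sharper
yield) and lowers ``beta`` (less plastic flow).  The maps are only
meaningful on the narrow ``(F, M)`` band the mineralization model visits
(``F`` near 0.8, ``M`` near 0.55); outside it they can return
non-physical ``n <= 0`` or ``E <= 0``, which is flagged with a
:class:`ValidityWarning` rather than clipped.

Toughness is the area under the stress–strain curve up to the ultimate
stress and splits into elastic energy (up to the yield point, by default
the standard 0.2% offset) and plastic energy.  All stresses/strains are in
the model's own nondimensional unit mix (modulus 10, ultimate stress 120);
no conversion to GPa/MPa is attempted.

A Kelvin–Voigt element (spring and dash-pot in parallel,
``sigma = E eps + eta deps/dt``) is included as a viscoelastic extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ValidityWarning",
    "RambergOsgoodParams",
    "StressStrainCurve",
    "KelvinVoigtParams",
    "EnergySplit",
    "material_properties",
    "ro_strain",
    "ro_stress",
    "stress_strain_curve",
    "energy_decomposition",
    "closed_form_toughness",
    "kelvin_voigt_stress",
    "creep_response",
]


class ValidityWarning(UserWarning):
    """Material parameters outside the physically meaningful domain."""


@dataclass(frozen=True)
class RambergOsgoodParams:
    """Parameters of the elasto-plastic law ``eps = s/E + beta (s/E)^n``."""

    E: float
    beta: float
    n: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("elastic modulus E must be positive")


@dataclass
class StressStrainCurve:
    """A monotone stress–strain curve with optional energy decomposition."""

    stresses: np.ndarray
    strains: np.ndarray
    params: RambergOsgoodParams
    we: float | None = None
    wp_mech: float | None = None
    toughness: float | None = None


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Spring stiffness and dash-pot viscosity of the parallel element."""

    E_spring: float
    eta_visc: float

    def __post_init__(self) -> None:
        if self.E_spring <= 0 or self.eta_visc <= 0:
            raise ValueError("spring stiffness and viscosity must be positive")


class EnergySplit(NamedTuple):
    we: float
    wp_mech: float
    toughness: float


class MaterialProperties(NamedTuple):
    n: float
    beta: float
    E: float


def material_properties(F: float, M: float) -> MaterialProperties:
    """Hardening exponent, plastic coefficient and modulus from ``(F, M)``.

    Warns (:class:`ValidityWarning`) when the maps leave their validity
    domain (``n <= 0`` or ``E <= 0``); values are returned unclipped.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError("maturity fraction F must lie in [0, 1]")
    if M < 0:
        raise ValueError("crystal count M must be non-negative")
    n = 30.0 * F**10 - 0.1 * M
    beta = -0.5 * F**5 + 0.85 * M
    E = -5.0 * F**2 + 10.0 * M
    if n <= 0 or E <= 0:
        warnings.warn(
            f"material maps out of validity domain at F={F:g}, M={M:g}: "
            f"n={n:g}, E={E:g}",
            ValidityWarning,
            stacklevel=2,
        )
    return MaterialProperties(n=n, beta=beta, E=E)


def ro_strain(sigma, params: RambergOsgoodParams):
    """Strain at stress ``sigma``: ``sigma/E + beta*(sigma/E)**n``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("stress must be non-negative")
    r = sigma / params.E
    with np.errstate(divide="ignore"):
        plastic = params.beta * np.where(r > 0, r**params.n, 0.0)
    out = r + plastic
    return out if out.ndim else float(out)


def ro_stress(strain: float, params: RambergOsgoodParams, sigma_hi: float | None = None) -> float:
    """Invert the law: stress at a given strain, by bracketed root finding.

    Requires ``beta >= 0`` (monotone curve).  ``sigma_hi`` optionally caps
    the search bracket.
    """
    if strain < 0:
        raise ValueError("strain must be non-negative")
    if strain == 0:
        return 0.0
    if params.beta < 0:
        raise ValueError("inversion requires beta >= 0 (monotone curve)")
    hi = sigma_hi if sigma_hi is not None else params.E * max(strain, 1.0)
    while ro_strain(hi, params) < strain:
        hi *= 2.0
    return float(brentq(lambda s: ro_strain(s, params) - strain, 0.0, hi, xtol=1e-14, rtol=1e-15))


def stress_strain_curve(
    F: float,
    M: float,
    sigma_max: float = 120.0,
    n_points: int = 1000,
    modulus_mode: str = "fixed",
    E_fixed: float = 10.0,
) -> StressStrainCurve:
    """Stress–strain curve for a microstructural state ``(F, M)``.

    ``modulus_mode="fixed"`` uses the constant modulus ``E_fixed`` with
    ``n, beta`` from the empirical maps; ``"coupled"`` also takes the
    modulus from its ``E(F, M)`` map.  The curve is evaluated on a uniform
    stress grid from 0 to ``sigma_max``.
    """
    if sigma_max <= 0:
        raise ValueError("sigma_max must be positive")
    if modulus_mode not in ("fixed", "coupled"):
        raise ValueError("modulus_mode must be 'fixed' or 'coupled'")
    n, beta, E_map = material_properties(F, M)
    E = E_map if modulus_mode == "coupled" else E_fixed
    params = RambergOsgoodParams(E=E, beta=beta, n=n)
    stresses = np.linspace(0.0, sigma_max, n_points)
    strains = ro_strain(stresses, params)
    if np.any(np.diff(strains) <= 0):
        warnings.warn(
            "stress-strain curve is not strictly increasing "
            f"(beta={beta:g}, n={n:g}); energies are unreliable",
            ValidityWarning,
            stacklevel=2,
        )
    return StressStrainCurve(stresses=stresses, strains=strains, params=params)


def closed_form_toughness(params: RambergOsgoodParams, sigma_max: float) -> float:
    """Analytic area under the curve up to ``sigma_max``.

    ``∫ sigma d eps = sigma_max*eps(sigma_max) - [sigma_max^2/(2E)
    + beta*E*(sigma_max/E)^{n+1}/(n+1)]`` (integration by parts).
    """
    e_ult = ro_strain(sigma_max, params)
    r = sigma_max / params.E
    return float(
        sigma_max * e_ult
        - (sigma_max**2 / (2.0 * params.E) + params.beta * params.E * r ** (params.n + 1.0) / (params.n + 1.0))
    )


def _offset_yield_stress(params: RambergOsgoodParams, sigma_max: float, offset: float = 0.002) -> float:
    """Stress where the plastic strain equals the 0.2% offset, by bisection."""
    if params.beta <= 0:
        return sigma_max  # no plastic branch: all elastic up to sigma_max
    g = lambda s: params.beta * (s / params.E) ** params.n - offset
    if g(sigma_max) <= 0:
        return sigma_max  # offset never reached in the sampled range
    return float(brentq(g, 0.0, sigma_max, xtol=1e-12))


def energy_decomposition(
    curve: StressStrainCurve, yield_method: str = "offset_0.2"
) -> EnergySplit:
    """Split the area under the curve into elastic and plastic energy.

    Toughness is computed by trapezoid quadrature on the curve and checked
    against the closed form (warning beyond 0.1% — refine the stress grid).
    Elastic energy is the stored strain energy at the yield stress,
    ``sigma_y^2 / (2E)``; with ``yield_method="none"`` the yield point is
    skipped and the elastic share is taken at ``sigma_max``.  Plastic
    energy is the remainder; ``toughness = we + wp_mech`` by construction.
    The decomposition mutates and returns the curve's energy fields.
    """
    if yield_method not in ("offset_0.2", "none"):
        raise ValueError("yield_method must be 'offset_0.2' or 'none'")
    if np.any(np.diff(curve.strains) <= 0):
        raise ValueError("energy decomposition requires a strictly monotone curve")
    tough_quad = float(np.trapezoid(curve.stresses, curve.strains))
    sigma_max = float(curve.stresses[-1])
    tough_cf = closed_form_toughness(curve.params, sigma_max)
    if tough_cf > 0 and abs(tough_quad - tough_cf) > 1e-3 * tough_cf:
        warnings.warn(
            f"quadrature toughness {tough_quad:g} deviates from closed form "
            f"{tough_cf:g} by more than 0.1%; increase n_points",
            stacklevel=2,
        )
    if yield_method == "offset_0.2":
        sigma_y = _offset_yield_stress(curve.params, sigma_max)
    else:
        sigma_y = sigma_max
    we = sigma_y**2 / (2.0 * curve.params.E)
    wp = tough_quad - we
    curve.we, curve.wp_mech, curve.toughness = we, wp, tough_quad
    return EnergySplit(we=we, wp_mech=wp, toughness=tough_quad)


def kelvin_voigt_stress(strain, strain_rate, params: KelvinVoigtParams):
    """Stress of the parallel spring/dash-pot: ``E*eps + eta*deps/dt``."""
    out = params.E_spring * np.asarray(strain, dtype=float) + params.eta_visc * np.asarray(
        strain_rate, dtype=float
    )
    return out if out.ndim else float(out)


def creep_response(sigma0: float, t, params: KelvinVoigtParams):
    """Strain under a constant stress step: ``(sigma0/E)(1 - e^{-E t/eta})``."""
    t = np.asarray(t, dtype=float)
    out = sigma0 / params.E_spring * (1.0 - np.exp(-params.E_spring * t / params.eta_visc))
    return out if out.ndim else float(out)
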