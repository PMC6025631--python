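"""Rate laws of the mineralization model.

Three pure functions drive the size-structured mineral equation:

* :func:`growth_velocity` — crystal growth speed ``V(s)`` as a function of
  the collagen maturity fraction ``s = F(t)``.  Growth is negligible while
  the matrix is immature and switches on sharply as ``F`` approaches 1.
* :func:`aggregation_rate` — the (size-independent) Smoluchowski kernel
  magnitude ``k(N, I, s)``: nucleators promote aggregation, inhibitors
  suppress it through a ``1/(1+I^2)`` factor.
* :func:`precipitation_density` — the boundary density of freshly
  precipitated crystals at size zero, a Hill-type switch in the inhibitor
  level damped exponentially by the number of crystals already present.

All quantities are nondimensional; the model is simulated in the source
data's own unit mix and no unit conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParameters",
    "growth_velocity",
    "aggregation_rate",
    "precipitation_density",
]

#: Allowed readings of the growth-velocity exponent grouping.
V_VARIANTS = ("onethird", "thirteen")
#: Allowed readings of the aggregation-kernel exponent grouping.
K_VARIANTS = ("joined", "split")


@dataclass(frozen=True)
class KineticParameters:
    """Parameters of the kinetic laws.

    Parameters
    ----------
    eta
        Damping coefficient of the precipitation boundary, ``exp(-eta*M)``.
        Dimensionless, default 0.2.
    alpha
        Collagen maturation age threshold separating immature from mature
        crosslinks (age units, default 3).
    b
        Half-saturation constant of the inhibitor Hill term, default 0.001.
    a_hill
        Inhibitor Hill exponent, default 10.
    v_variant, k_variant
        Which de-flattening of the printed velocity/kernel formulas to use.
        ``"onethird"``/``"joined"`` are the defaults adopted here;
        ``"thirteen"`` groups the velocity exponent as ``(s+13)**2`` and
        ``"split"`` reads the kernel tail as ``exp(-10 s**2) + s``.  The
        alternates exist so qualitative comparisons can be run under each
        plausible reading.
    """

    eta: float = 0.2
    alpha: float = 3.0
    b: float = 1e-3
    a_hill: float = 10.0
    v_variant: str = "onethird"
    k_variant: str = "joined"

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.a_hill < 1:
            raise ValueError("a_hill must be >= 1")
        if self.v_variant not in V_VARIANTS:
            raise ValueError(f"v_variant must be one of {V_VARIANTS}")
        if self.k_variant not in K_VARIANTS:
            raise ValueError(f"k_variant must be one of {K_VARIANTS}")


_DEFAULT = KineticParameters()


def growth_velocity(s, params: KineticParameters = _DEFAULT):
    """Crystal growth speed ``V(s)`` at maturity fraction ``s``.

    Default reading: ``V(s) = s**50 * exp(-0.5*(s + 1/3)**2)``.  The huge
    power keeps growth essentially zero until the collagen matrix is almost
    fully mature (``V(0.5) ~ 6e-16``) and then lets it switch on.

    Note that ``V(1) = exp(-8/9) > 0``: the printed law does not vanish at
    full maturity even though the modelling narrative asks for ``V(1)=0``.
    The function is implemented exactly as printed.

    Parameters
    ----------
    s
        Maturity fraction, scalar or array, each value in ``[0, 1]``.

    Returns
    -------
    Growth speed (size/time), same shape as ``s``.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("maturity fraction s must lie in [0, 1]")
    if params.v_variant == "onethird":
        out = s**50 * np.exp(-0.5 * (s + 1.0 / 3.0) ** 2)
    else:  # "thirteen"
        out = s**50 * np.exp(-0.5 * (s + 13.0) ** 2)
    return out if out.ndim else float(out)


def aggregation_rate(N, I, s, params: KineticParameters = _DEFAULT):
    """Constant-kernel aggregation magnitude ``k(N, I, s)``.

    Default reading: ``k = [10*N / (1 + I**2)] * s * exp(-10*s**2 + s)``.
    Linear in the nucleator level ``N``, decreasing in the inhibitor level
    ``I``, and zero at ``s = 0`` (no aggregation in a fully immature
    matrix).  The kernel is independent of the sizes of the two joining
    crystals.

    Parameters
    ----------
    N, I
        Nucleator and inhibitor levels, both ``>= 0``.
    s
        Maturity fraction in ``[0, 1]``.
    """
    N = np.asarray(N, dtype=float)
    I = np.asarray(I, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(N < 0) or np.any(I < 0):
        raise ValueError("N and I must be non-negative")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("maturity fraction s must lie in [0, 1]")
    front = 10.0 * N / (1.0 + I**2)
    if params.k_variant == "joined":
        out = front * s * np.exp(-10.0 * s**2 + s)
    else:  # "split"
        out = front * s * (np.exp(-10.0 * s**2) + s)
    return out if out.ndim else float(out)


def precipitation_density(N, I, M, params: KineticParameters = _DEFAULT):
    """Boundary density of freshly precipitated crystals at size zero.

    ``m(t, 0) = 0.001*N / (0.001 + I**a) * exp(-eta*M)`` with Hill exponent
    ``a``: nucleators drive precipitation linearly, inhibitors shut it off
    sharply once ``I**a`` exceeds the half-saturation constant ``b``, and
    the ``exp(-eta*M)`` factor throttles precipitation as crystals
    accumulate.

    Parameters
    ----------
    N, I
        Nucleator and inhibitor levels, ``>= 0``.
    M
        Total crystal count (zeroth moment of the size density), ``>= 0``.
    """
    N = np.asarray(N, dtype=float)
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(N < 0) or np.any(I < 0) or np.any(M < 0):
        raise ValueError("N, I and M must be non-negative")
    hill = _hill_power(I, params.a_hill)
    out = params.b * N / (params.b + hill) * np.exp(-params.eta * M)
    return out if out.ndim else float(out)


def _hill_power(I, a: float):
    """``I**a`` computed in log space for large ``I`` to avoid overflow."""
    I = np.asarray(I, dtype=float)
    small = np.minimum(I, 1e3) ** a
    with np.errstate(divide="ignore"):
        big = np.exp(np.clip(a * np.log(np.maximum(I, 1e-300)), None, 700.0))
    return np.where(I > 1e3, big, small)
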