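"""Closed-form rate laws and response functions.

The central model is the ping-pong bi-bi (substituted-enzyme) rate law for a
two-substrate reductase reaction, with an optional substrate-inhibition term
for the electron acceptor:

    v = E0 * kcat * [A][B] / ( K_A*[B]*(1 + [B]/K_I) + K_B*[A] + [A][B] )

where A is the reducing cosubstrate (BNAH, NADH, NADPH, ...), B is the
electron acceptor (menadione), K_A and K_B are the Michaelis constants,
K_I is the acceptor substrate-inhibition constant, and E0 the total enzyme
concentration.  Concentrations are in µM, E0 is supplied in nM, kcat in s⁻¹,
so observed velocities come out in µM·s⁻¹.

Also here: the variable-slope four-parameter logistic used for cell-viability
dose-response curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "RateLawParams",
    "DoseResponseParams",
    "pingpong_rate",
    "apparent_mm_rate",
    "logistic_response",
]


@dataclass(frozen=True)
class RateLawParams:
    """Kinetic constants for one enzyme/cosubstrate pair.

    Parameters
    ----------
    kcat : float
        Turnover number, s⁻¹.
    K_A : float
        Michaelis constant of the reducing cosubstrate, µM.
    K_B : float
        Michaelis constant of the electron acceptor (menadione), µM.
    K_I : float, optional
        Substrate-inhibition constant of the acceptor, µM.  ``None`` means
        no inhibition term (the (1 + B/K_I) factor is 1).
    E0 : float
        Total enzyme concentration, nM.
    """

    kcat: float
    K_A: float
    K_B: float
    K_I: Optional[float] = None
    E0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kcat > 0):
            raise ValueError(f"kcat must be positive, got {self.kcat}")
        if not (self.K_A > 0):
            raise ValueError(f"K_A must be positive, got {self.K_A}")
        if not (self.K_B > 0):
            raise ValueError(f"K_B must be positive, got {self.K_B}")
        if self.K_I is not None and not (self.K_I > 0):
            raise ValueError(f"K_I must be positive when present, got {self.K_I}")
        if not (self.E0 > 0):
            raise ValueError(f"E0 must be positive, got {self.E0}")

    @property
    def e0_uM(self) -> float:
        """Enzyme concentration converted from nM to µM."""
        return self.E0 * 1e-3

    @property
    def vmax(self) -> float:
        """Saturating velocity E0·kcat in µM·s⁻¹."""
        return self.e0_uM * self.kcat

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/K_A in M⁻¹·s⁻¹."""
        return self.kcat / (self.K_A * 1e-6)

    def with_(self, **changes) -> "RateLawParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class DoseResponseParams:
    """Four-parameter logistic (variable slope) dose-response parameters.

    top/bottom are upper/lower asymptotes on the normalized-viability scale,
    ic50 in µM, hill the dimensionless slope factor.
    """

    top: float
    bottom: float
    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.top > self.bottom):
            raise ValueError(f"top must exceed bottom ({self.top} <= {self.bottom})")
        if not (self.ic50 > 0):
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if not (self.hill > 0):
            raise ValueError(f"hill must be positive, got {self.hill}")


def _check_nonneg(x: np.ndarray, name: str) -> None:
    if np.any(x < 0):
        raise ValueError(f"{name} concentrations must be non-negative")


def pingpong_rate(params: RateLawParams, a, b):
    """Ping-pong bi-substrate velocity at cosubstrate ``a`` and acceptor ``b`` (µM).

    Returns the observed velocity in µM·s⁻¹ (E0-scaled).  Accepts scalars or
    arrays; zero concentration of either substrate gives zero rate.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    _check_nonneg(a_arr, "cosubstrate")
    _check_nonneg(b_arr, "acceptor")

    inhib = 1.0 + b_arr / params.K_I if params.K_I is not None else 1.0
    num = params.vmax * a_arr * b_arr
    den = params.K_A * b_arr * inhib + params.K_B * a_arr + a_arr * b_arr
    den = np.where(den > 0, den, 1.0)  # a=b=0 limit: numerator is already 0
    out = num / den
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


def apparent_mm_rate(params: RateLawParams, a, b_fixed: float):
    """Apparent single-cosubstrate Michaelis-Menten velocity at fixed acceptor.

    Identical to :func:`pingpong_rate` evaluated at ``b = b_fixed``; exposed
    separately so that fits over the cosubstrate alone treat the acceptor
    constants (K_B and, if present, K_I) as frozen.
    """
    if params.K_B is None:  # pragma: no cover - K_B is a mandatory field
        raise ValueError("frozen acceptor Michaelis constant K_B is required")
    if not (b_fixed > 0):
        raise ValueError(f"b_fixed must be positive, got {b_fixed}")
    return pingpong_rate(params, a, b_fixed)


def logistic_response(params: DoseResponseParams, conc):
    """Four-parameter logistic viability at drug concentration ``conc`` (µM).

    bottom + (top - bottom) / (1 + (conc/ic50)**hill); conc = 0 returns top.
    """
    c = np.asarray(conc, dtype=float)
    _check_nonneg(c, "drug")
    out = params.bottom + (params.top - params.bottom) / (
        1.0 + (c / params.ic50) ** params.hill
    )
    if np.isscalar(conc):
        return float(out)
    return out
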