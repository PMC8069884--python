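"""Structural model of subcutaneous insulin lispro kinetics and the residual
error model.

The structural model is a linear three-compartment system. Insulin is
injected as a bolus into a subcutaneous non-monomeric pool ``Isc1`` after a
subject-specific delay ``tau``; from there it either dissociates into a
monomeric pool ``Isc2`` (rate ``kd``) or is absorbed directly into plasma
(rate ``ka1``). Monomeric insulin is absorbed with rate ``ka2`` and plasma
insulin ``Ip`` is eliminated with rate ``ke``. The observed quantity is the
plasma concentration ``y = Ip / VI`` in μU/mL, with ``VI`` the distribution
volume per kg body weight.

Because ``kd`` and ``ka2`` are interchangeable the model is reparameterized
with ``alpha = kd - ka2 > 0`` (so ``kd = alpha + ka2 >= ka2`` by
construction), which removes the permutation ambiguity.

Measurement error is heteroscedastic: SD(y) = sqrt(a² + b²·y²), combining an
additive assay floor ``a`` (μU/mL) and a proportional component ``b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PKParams",
    "DoseEvent",
    "ErrorParams",
    "solve_pk",
    "solve_pk_states",
    "residual_sd",
    "iwres",
]

#: Canonical ordering of the six kinetic parameters throughout the package.
PARAM_NAMES = ("tau", "VI", "alpha", "ka1", "ka2", "ke")

#: Two rate constants closer than this (min⁻¹) are nudged apart before the
#: closed form is evaluated (eigenvalue coincidence is a measure-zero event
#: under the log-normal population model).
RATE_DEGENERACY_TOL = 1e-10

_UU_PER_U = 1.0e6  # μU per insulin unit
_ML_PER_L = 1.0e3


@dataclass(frozen=True)
class PKParams:
    """One subject's kinetic parameters.

    Units: ``tau`` min; ``VI`` L/kg; ``alpha``, ``ka1``, ``ka2``, ``ke``
    min⁻¹. The dissociation rate ``kd = alpha + ka2`` is derived.
    """

    tau: float
    VI: float
    alpha: float
    ka1: float
    ka2: float
    ke: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def kd(self) -> float:
        """Dissociation rate (min⁻¹); ≥ ka2 because alpha > 0."""
        return self.alpha + self.ka2

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "PKParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass(frozen=True)
class DoseEvent:
    """A single subcutaneous bolus.

    ``amount`` is in insulin units (U); if ``per_kg`` it is U per kg body
    weight (weight-based dosing). ``time`` is minutes on the study clock.
    """

    amount: float
    time: float = 0.0
    per_kg: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount) or self.amount <= 0.0:
            raise ValueError(f"dose amount must be > 0, got {self.amount!r}")
        if not math.isfinite(self.time):
            raise ValueError("dose time must be finite")

    def amount_uU_per_kg(self, body_weight: float) -> float:
        """Dose in μU per kg body weight."""
        if self.per_kg:
            return self.amount * _UU_PER_U
        return self.amount * _UU_PER_U / body_weight


@dataclass(frozen=True)
class ErrorParams:
    """Combined additive (``a``, μU/mL) + proportional (``b``) error model."""

    a: float
    b: float
    study: str = ""

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("error parameters must be non-negative")
        if self.a == 0 and self.b == 0:
            raise ValueError("a and b cannot both be zero")


def _separated_rates(lam1: float, lam2: float, lam3: float) -> tuple[float, float, float]:
    """Nudge near-coincident rate constants apart by the degeneracy tolerance."""
    tol = RATE_DEGENERACY_TOL
    for _ in range(4):
        moved = False
        if abs(lam1 - lam2) < tol:
            lam1 += tol
            moved = True
        if abs(lam3 - lam2) < tol:
            lam3 += tol
            moved = True
        if abs(lam3 - lam1) < tol:
            lam3 += 2.0 * tol
            moved = True
        if not moved:
            return lam1, lam2, lam3
    return lam1, lam2, lam3


def solve_pk_states(
    params: PKParams,
    dose: DoseEvent,
    times: np.ndarray,
    body_weight: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form state trajectories (Isc1, Isc2, Ip) in μU per kg BW.

    The bolus enters Isc1 at ``dose.time + tau``; all states are zero
    before that. The linear system has eigenvalues ``-(ka1+kd)``, ``-ka2``
    and ``-ke``, so each state is a sum of at most three exponentials.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    if not math.isfinite(body_weight) or body_weight <= 0:
        raise ValueError("body_weight must be > 0")

    D = dose.amount_uU_per_kg(body_weight)
    lam1, lam2, lam3 = _separated_rates(params.ka1 + params.kd, params.ka2, params.ke)
    kd, ka1, ka2 = params.kd, params.ka1, params.ka2

    s = t - (dose.time + params.tau)
    active = s > 0
    sa = np.where(active, s, 0.0)

    e1 = np.exp(-lam1 * sa)
    e2 = np.exp(-lam2 * sa)
    e3 = np.exp(-lam3 * sa)

    isc1 = D * e1
    isc2 = D * kd * (e2 - e1) / (lam1 - lam2)
    # Plasma: direct path from Isc1 plus the two-stage path through Isc2.
    ip = ka1 * D * (e1 - e3) / (lam3 - lam1) + ka2 * D * kd / (lam1 - lam2) * (
        (e2 - e3) / (lam3 - lam2) - (e1 - e3) / (lam3 - lam1)
    )
    zero = ~active
    isc1[zero] = 0.0
    isc2[zero] = 0.0
    ip[zero] = 0.0
    return isc1, isc2, ip


def solve_pk(
    params: PKParams,
    dose: DoseEvent,
    times: np.ndarray,
    body_weight: float,
) -> np.ndarray:
    """Plasma insulin concentration (μU/mL) at ``times`` (min post dose).

    ``y(t) = Ip(t) / VI`` with Ip in μU/kg and VI converted to mL/kg, so the
    result is directly comparable to assay readings. The total exposure obeys
    ∫₀^∞ y dt = D / (ke · VI · BW).
    """
    _, _, ip = solve_pk_states(params, dose, times, body_weight)
    return ip / (params.VI * _ML_PER_L)


def residual_sd(y, err: ErrorParams):
    """Measurement-error SD, sqrt(a² + b²·y²), at predicted concentration y."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("predicted concentration must be non-negative")
    out = np.sqrt(err.a**2 + err.b**2 * y**2)
    return float(out) if out.ndim == 0 else out


def iwres(z, y_hat, err: ErrorParams):
    """Individual weighted residual: (z − ŷ) / sqrt(a² + b²·ŷ²)."""
    z = np.asarray(z, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    out = (z - y_hat) / residual_sd(y_hat, err)
    return float(out) if out.ndim == 0 else out
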