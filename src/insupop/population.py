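"""Between-subject variability model.

Individual kinetic parameters are log-normal around population values, with
optional covariate effects on the log scale and correlated Gaussian random
effects:

    psi_ij = theta_i * exp( sum_k beta_{k,i} (c_kj - cbar_k) + eta_ij ),
    eta_j ~ N(0, Omega).

Covariates are centered at a reference (the database mean), so each beta is
the log-scale shift per unit covariate deviation. The candidate variability
models differ only in which covariate links and which random-effect
correlations they include; the 14 candidates used in the published analysis
are exposed by :func:`candidate_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import PARAM_NAMES, PKParams

__all__ = [
    "CovariateVector",
    "CovariateLink",
    "FixedEffects",
    "RandomEffectSpec",
    "ModelSpec",
    "candidate_models",
    "derive_covariates",
    "build_omega",
    "individual_params",
    "sample_eta",
]

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

COVARIATE_NAMES = ("AGE", "BW", "BH", "BMI", "BSA")


@dataclass(frozen=True)
class CovariateVector:
    """Demographic/anthropometric covariates of one subject.

    AGE years, BW kg, BH cm, BMI kg/m², BSA m².
    """

    AGE: float
    BW: float
    BH: float
    BMI: float
    BSA: float

    def __post_init__(self) -> None:
        for name in COVARIATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"covariate {name} must be finite and > 0, got {v!r}")
        implied_bmi = self.BW / (self.BH / 100.0) ** 2
        if abs(implied_bmi - self.BMI) > 0.02 * implied_bmi:
            raise ValueError(
                f"BMI {self.BMI:.2f} inconsistent with BW/BH (implies {implied_bmi:.2f})"
            )

    def value(self, name: str, log: bool = False) -> float:
        v = getattr(self, name)
        return math.log(v) if log else v


def derive_covariates(BW: float, BH: float, AGE: float) -> CovariateVector:
    """Derive BMI and Du Bois BSA from body weight (kg) and height (cm).

    BMI = BW / (BH/100)²;  BSA = 0.007184 · BW^0.425 · BH^0.725.
    """
    if BW <= 0 or BH <= 0 or AGE <= 0:
        raise ValueError("BW, BH and AGE must be positive")
    bmi = BW / (BH / 100.0) ** 2
    bsa = 0.007184 * BW**0.425 * BH**0.725
    return CovariateVector(AGE=AGE, BW=BW, BH=BH, BMI=bmi, BSA=bsa)


@dataclass(frozen=True)
class CovariateLink:
    """One covariate → parameter link: beta multiplies (c − c̄), or
    (ln c − ln c̄) when ``log`` is set."""

    covariate: str
    param: str
    log: bool = False

    def __post_init__(self) -> None:
        if self.covariate not in COVARIATE_NAMES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.param not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.param!r}")

    @property
    def label(self) -> str:
        c = f"ln({self.covariate})" if self.log else self.covariate
        return f"beta_{c},{self.param}"


@dataclass(frozen=True)
class ModelSpec:
    """A candidate variability model: covariate links + correlation pairs."""

    id: int
    links: tuple[CovariateLink, ...] = ()
    corr_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for p1, p2 in self.corr_pairs:
            if p1 not in PARAM_NAMES or p2 not in PARAM_NAMES or p1 == p2:
                raise ValueError(f"invalid correlation pair ({p1}, {p2})")
            key = frozenset((p1, p2))
            if key in seen:
                raise ValueError(f"duplicate correlation pair ({p1}, {p2})")
            seen.add(key)

    @property
    def n_beta(self) -> int:
        return len(self.links)

    @property
    def n_rho(self) -> int:
        return len(self.corr_pairs)


def candidate_models() -> dict[int, ModelSpec]:
    """The 14 candidate variability models.

    Model 1 is diagonal Omega with no covariates; Model 2 adds the VI–ka2
    correlation; Model 3 the full VI/ka2/ke correlation block; Models 4–14
    add covariate links on top of Model 3.
    """
    rho3 = (("VI", "ka2"), ("VI", "ke"), ("ka2", "ke"))
    L = CovariateLink
    return {
        1: ModelSpec(1),
        2: ModelSpec(2, corr_pairs=(("VI", "ka2"),)),
        3: ModelSpec(3, corr_pairs=rho3),
        4: ModelSpec(4, links=(L("AGE", "tau", log=True),), corr_pairs=rho3),
        5: ModelSpec(5, links=(L("BMI", "VI"),), corr_pairs=rho3),
        6: ModelSpec(6, links=(L("BMI", "ke"),), corr_pairs=rho3),
        7: ModelSpec(7, links=(L("BSA", "ka2"),), corr_pairs=rho3),
        8: ModelSpec(8, links=(L("BMI", "tau"),), corr_pairs=rho3),
        9: ModelSpec(9, links=(L("BW", "ka2"),), corr_pairs=rho3),
        10: ModelSpec(10, links=(L("BW", "ka2", log=True),), corr_pairs=rho3),
        11: ModelSpec(11, links=(L("BMI", "ka2"),), corr_pairs=rho3),
        12: ModelSpec(12, links=(L("BMI", "tau"), L("BMI", "ka2")), corr_pairs=rho3),
        13: ModelSpec(13, links=(L("BH", "ka2"), L("BW", "ka2")), corr_pairs=rho3),
        14: ModelSpec(14, links=(L("BMI", "ka2"), L("AGE", "tau", log=True)), corr_pairs=rho3),
    }


@dataclass(frozen=True)
class FixedEffects:
    """Population-typical parameter values plus covariate coefficients.

    ``pop`` maps each kinetic parameter name to its population value (units
    of :class:`~insupop.model_core.PKParams`); ``beta`` maps each active
    :class:`CovariateLink` to its coefficient.
    """

    pop: dict[str, float]
    beta: dict[CovariateLink, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.pop) != set(PARAM_NAMES):
            raise ValueError(f"pop must define exactly {PARAM_NAMES}")
        for name, v in self.pop.items():
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"population value {name} must be > 0, got {v!r}")
        for link, b in self.beta.items():
            if not math.isfinite(b):
                raise ValueError(f"{link.label} must be finite")

    def pop_array(self) -> np.ndarray:
        return np.array([self.pop[n] for n in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class RandomEffectSpec:
    """Log-scale SDs of the six random effects plus declared correlations."""

    omega: tuple[float, ...]
    rho: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.omega) != len(PARAM_NAMES):
            raise ValueError(f"omega must have {len(PARAM_NAMES)} entries")
        if any((not math.isfinite(w)) or w < 0 for w in self.omega):
            raise ValueError("omega entries must be finite and >= 0")
        for (p1, p2), r in self.rho.items():
            if p1 not in PARAM_NAMES or p2 not in PARAM_NAMES:
                raise ValueError(f"unknown parameter in correlation ({p1}, {p2})")
            if not -1.0 < r < 1.0:
                raise ValueError(f"rho({p1},{p2}) must be in (-1, 1), got {r!r}")

    def omega_array(self) -> np.ndarray:
        return np.asarray(self.omega, dtype=float)


def build_omega(spec: RandomEffectSpec) -> np.ndarray:
    """Assemble the 6×6 random-effect covariance matrix Omega.

    Diagonal entries are ω_i²; an off-diagonal entry is ω_i ω_j ρ(i,j) for
    each declared pair and zero elsewhere. Raises if the result is not
    positive semi-definite.
    """
    w = spec.omega_array()
    omega = np.diag(w**2)
    for (p1, p2), r in spec.rho.items():
        i, j = _PARAM_INDEX[p1], _PARAM_INDEX[p2]
        omega[i, j] = omega[j, i] = w[i] * w[j] * r
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals[0] < -1e-10 * max(eigvals[-1], 1.0):
        raise ValueError(
            f"assembled Omega is not positive semi-definite "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        )
    return omega


def individual_params(
    theta: FixedEffects,
    spec: ModelSpec,
    cov: CovariateVector,
    cov_ref: CovariateVector,
    eta: np.ndarray,
) -> PKParams:
    """Map (fixed effects, covariates, random effects) to one subject's
    kinetic parameters; ``kd`` is derived as ``alpha + ka2`` afterwards."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(PARAM_NAMES),):
        raise ValueError(f"eta must be a {len(PARAM_NAMES)}-vector")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    log_psi = np.log(theta.pop_array()) + eta
    for link in spec.links:
        beta = theta.beta.get(link)
        if beta is None:
            raise ValueError(f"missing coefficient for {link.label}")
        delta = cov.value(link.covariate, link.log) - cov_ref.value(link.covariate, link.log)
        log_psi[_PARAM_INDEX[link.param]] += beta * delta
    return PKParams.from_array(np.exp(log_psi))


def sample_eta(spec: RandomEffectSpec, n: int, seed) -> np.ndarray:
    """Draw n random-effect vectors from N(0, Omega); reproducible by seed."""
    omega = build_omega(spec)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(
        np.zeros(len(PARAM_NAMES)), omega, size=int(n), method="svd"
    )
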