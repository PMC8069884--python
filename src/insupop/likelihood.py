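"""Likelihood building blocks for the hierarchical model.

The estimation code works on a *stacked* representation of the data
(:class:`NLMEProblem`): observations padded into (n_subjects, max_times)
arrays so that structural predictions, observation log-likelihoods and
Metropolis–Hastings transitions are vectorized across subjects. The same
machinery is generic in the latent dimension and in the structural
predictor, so conjugate linear-Gaussian toys exercise the identical code
path as the insulin model.

Per-subject conditional density:  log p(z_j | eta_j) + log p(eta_j), with
observation SDs from the combined error model and a N(0, Omega) prior on
the random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gammaln, logsumexp

from .model_core import PARAM_NAMES, ErrorParams, RATE_DEGENERACY_TOL
from .population import (
    CovariateVector,
    FixedEffects,
    ModelSpec,
    RandomEffectSpec,
    build_omega,
    individual_params,
)

__all__ = [
    "NLMEProblem",
    "build_problem",
    "conditional_logdensity",
    "mcmc_sample_eta",
    "MHState",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Stacked problem representation
# ---------------------------------------------------------------------------

@dataclass
class NLMEProblem:
    """Stacked dataset + structural predictor for vectorized inference.

    ``predict(phi, rows)`` maps latent vectors ``phi`` (n_rows, d) — log
    individual parameters for the insulin model — and the subject index of
    each row to predictions on that subject's (padded) time grid.
    """

    times: np.ndarray          # (N, T) padded observation times
    obs: np.ndarray            # (N, T) padded observations
    mask: np.ndarray           # (N, T) True where a real observation exists
    study_idx: np.ndarray      # (N,) index into study_labels
    study_labels: tuple[str, ...]
    design: np.ndarray         # (N, d, q) per-subject design A_j, phi_mean = A_j @ xi
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray]
    d: int                     # latent dimension
    q: int                     # number of mean-model coefficients (d + n_beta)
    error_model: str = "combined"   # "combined" | "constant" | "proportional"
    subject_ids: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.times.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def n_obs_per_subject(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    # -- observation log-likelihood -------------------------------------

    def error_sd(self, y: np.ndarray, rows: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        s = self.study_idx[rows]
        return np.sqrt(a[s, None] ** 2 + b[s, None] ** 2 * y**2)

    def obs_loglik(
        self,
        phi: np.ndarray,
        rows: np.ndarray,
        a: np.ndarray,
        b: np.ndarray,
    ) -> np.ndarray:
        """Gaussian observation log-likelihood per row (vector of length n_rows)."""
        y = self.predict(phi, rows)
        s = self.study_idx[rows]
        sigma2 = a[s, None] ** 2 + b[s, None] ** 2 * y**2
        z = self.obs[rows]
        m = self.mask[rows]
        r2 = z - y
        r2 *= r2
        with np.errstate(divide="ignore"):
            ll = np.log(sigma2)
            ll += r2 / sigma2
            ll += _LOG_2PI
        ll *= -0.5
        return np.where(m, ll, 0.0).sum(axis=1)


def _eta_prior_loglik(eta: np.ndarray, oinv: np.ndarray, logdet: float, active: np.ndarray) -> np.ndarray:
    """N(0, Omega) log-density over the active random-effect dimensions."""
    e = eta[:, active]
    quad = np.einsum("ni,ij,nj->n", e, oinv, e)
    k = int(active.sum())
    return -0.5 * (k * _LOG_2PI + logdet + quad)


def prior_terms(omega: np.ndarray, active: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of the active block of Omega."""
    block = omega[np.ix_(active, active)]
    sign, logdet = np.linalg.slogdet(block)
    if sign <= 0:
        raise np.linalg.LinAlgError("Omega active block is singular")
    return np.linalg.inv(block), logdet


# ---------------------------------------------------------------------------
# Building the insulin problem from a Dataset
# ---------------------------------------------------------------------------

def _insulin_predictor(
    times: np.ndarray,
    dose_uU_per_kg: np.ndarray,
    dose_time: np.ndarray,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Vectorized closed-form concentration for log-parameter rows."""

    def predict(phi: np.ndarray, rows: np.ndarray) -> np.ndarray:
        p = np.exp(phi)
        tau, vi, alpha, ka1, ka2, ke = (p[:, i] for i in range(6))
        kd = alpha + ka2
        lam1 = ka1 + kd
        lam2 = ka2.copy()
        lam3 = ke.copy()
        tol = RATE_DEGENERACY_TOL
        lam1 = np.where(np.abs(lam1 - lam2) < tol, lam1 + tol, lam1)
        lam3 = np.where(np.abs(lam3 - lam2) < tol, lam3 + tol, lam3)
        lam3 = np.where(np.abs(lam3 - lam1) < tol, lam3 + 2 * tol, lam3)

        t = times[rows]
        s = t - (dose_time[rows] + tau)[:, None]
        act = s > 0
        sa = np.where(act, s, 0.0)
        e1 = np.exp(-lam1[:, None] * sa)
        e2 = np.exp(-lam2[:, None] * sa)
        e3 = np.exp(-lam3[:, None] * sa)
        D = dose_uU_per_kg[rows]
        c1 = (ka1 * D / (lam3 - lam1))[:, None]
        c2 = (ka2 * D * kd / (lam1 - lam2))[:, None]
        ip = c1 * (e1 - e3) + c2 * ((e2 - e3) / (lam3 - lam2)[:, None] - (e1 - e3) / (lam3 - lam1)[:, None])
        y = np.where(act, ip, 0.0) / (vi[:, None] * 1.0e3)
        return y

    return predict


def build_problem(dataset, spec: ModelSpec, cov_ref: CovariateVector | None = None) -> NLMEProblem:
    """Stack a :class:`~insupop.datasets.Dataset` for the insulin model.

    The design matrix of each subject carries an identity block for the six
    log population values plus one column per covariate link holding the
    centered covariate value.
    """
    subjects = dataset.subjects
    if cov_ref is None:
        cov_ref = dataset.mean_covariates()
    n = len(subjects)
    max_t = max(len(s.times) for s in subjects)
    times = np.zeros((n, max_t))
    obs = np.zeros((n, max_t))
    mask = np.zeros((n, max_t), dtype=bool)
    study_labels = tuple(sorted({s.study for s in subjects}))
    study_index = {lab: i for i, lab in enumerate(study_labels)}
    study_idx = np.zeros(n, dtype=int)
    dose_amt = np.zeros(n)
    dose_time = np.zeros(n)
    d = len(PARAM_NAMES)
    q = d + spec.n_beta
    design = np.zeros((n, d, q))
    pidx = {name: i for i, name in enumerate(PARAM_NAMES)}
    for j, s in enumerate(subjects):
        k = len(s.times)
        times[j, :k] = s.times
        obs[j, :k] = s.conc
        mask[j, :k] = True
        study_idx[j] = study_index[s.study]
        dose_amt[j] = s.dose.amount_uU_per_kg(s.covariates.BW)
        dose_time[j] = s.dose.time
        design[j, :, :d] = np.eye(d)
        for c, link in enumerate(spec.links):
            delta = s.covariates.value(link.covariate, link.log) - cov_ref.value(
                link.covariate, link.log
            )
            design[j, pidx[link.param], d + c] = delta
    return NLMEProblem(
        times=times,
        obs=obs,
        mask=mask,
        study_idx=study_idx,
        study_labels=study_labels,
        design=design,
        predict=_insulin_predictor(times, dose_amt, dose_time),
        d=d,
        q=q,
        subject_ids=tuple(s.id for s in subjects),
    )


# ---------------------------------------------------------------------------
# Public per-subject conditional density (reference scalar path)
# ---------------------------------------------------------------------------

def conditional_logdensity(
    subject,
    eta: np.ndarray,
    theta: FixedEffects,
    spec: ModelSpec,
    omega: np.ndarray | RandomEffectSpec,
    err: ErrorParams,
    cov_ref: CovariateVector | None = None,
) -> float:
    """log p(z_j | eta) + log p(eta) for one subject.

    This is the straightforward scalar implementation (one structural solve
    per call); the SAEM engine uses the equivalent vectorized path.
    """
    from .model_core import solve_pk

    if isinstance(omega, RandomEffectSpec):
        omega = build_omega(omega)
    eta = np.asarray(eta, dtype=float)
    if cov_ref is None:
        cov_ref = subject.covariates
    params = individual_params(theta, spec, subject.covariates, cov_ref, eta)

    active = np.sqrt(np.diag(omega)) > 0
    oinv, logdet = prior_terms(omega, active)
    if np.any(np.abs(eta[~active]) > 0):
        raise ValueError("eta has mass on a zero-variance random effect")
    e = eta[active]
    lp = -0.5 * (e @ oinv @ e + logdet + int(active.sum()) * _LOG_2PI)

    times = np.asarray(subject.times, dtype=float)
    if times.size:
        y = solve_pk(params, subject.dose, times, subject.covariates.BW)
        sd = np.sqrt(err.a**2 + err.b**2 * y**2)
        z = np.asarray(subject.conc, dtype=float)
        lp += float(np.sum(-0.5 * (_LOG_2PI + 2 * np.log(sd) + ((z - y) / sd) ** 2)))
    return float(lp)


# ---------------------------------------------------------------------------
# Metropolis–Hastings kernel (vectorized across subjects)
# ---------------------------------------------------------------------------

@dataclass
class MHState:
    """Persistent state of the per-subject random-walk MH chains."""

    eta: np.ndarray          # (N, d)
    logp_obs: np.ndarray     # (N,) cached observation log-likelihoods
    step_full: np.ndarray    # (N,) full-vector proposal scales
    step_comp: np.ndarray    # (N, d) componentwise proposal scales
    n_accept: int = 0
    n_propose: int = 0

    @classmethod
    def initial(cls, n: int, d: int) -> "MHState":
        return cls(
            eta=np.zeros((n, d)),
            logp_obs=np.full(n, -np.inf),
            step_full=np.full(n, 0.4),
            step_comp=np.full((n, d), 0.8),
        )


def mh_transition(
    problem: NLMEProblem,
    state: MHState,
    omega: np.ndarray,
    xi: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    adapt: float = 0.05,
    target_accept: float = 0.3,
) -> None:
    """One full-vector proposal plus one componentwise sweep, in place.

    Targets p(eta_j | z_j) for every subject simultaneously; proposal scales
    adapt (Robbins–Monro on the log scale) toward the target acceptance.
    """
    n, d = state.eta.shape
    rows = np.arange(n)
    active = np.sqrt(np.diag(omega)) > 0
    oinv, logdet = prior_terms(omega, active)

    def phi_of(eta: np.ndarray) -> np.ndarray:
        return np.einsum("ndq,q->nd", problem.design, xi) + eta

    # xi / Omega / error parameters change between SAEM iterations, so the
    # cached target values must be refreshed before proposing.
    state.logp_obs = problem.obs_loglik(phi_of(state.eta), rows, a, b)

    block = omega[np.ix_(active, active)]
    chol = np.linalg.cholesky(block + 1e-12 * np.eye(int(active.sum())))

    # independence proposal from the marginal N(0, Omega): the prior and
    # proposal densities cancel, so the ratio is the observation term
    # alone. Acceptance is low for data-rich subjects, but it lets a chain
    # stuck in a minor mode (delay multimodality) jump out.
    prop = np.zeros_like(state.eta)
    prop[:, active] = rng.standard_normal((n, int(active.sum()))) @ chol.T
    lp_obs_new = problem.obs_loglik(phi_of(prop), rows, a, b)
    accept = np.log(rng.random(n)) < lp_obs_new - state.logp_obs
    state.eta[accept] = prop[accept]
    state.logp_obs[accept] = lp_obs_new[accept]
    state.n_accept += int(accept.sum())
    state.n_propose += n

    logp_pri = _eta_prior_loglik(state.eta, oinv, logdet, active)
    z = rng.standard_normal((n, int(active.sum())))
    prop = state.eta.copy()
    prop[:, active] = state.eta[:, active] + state.step_full[:, None] * (z @ chol.T)
    lp_obs_new = problem.obs_loglik(phi_of(prop), rows, a, b)
    lp_pri_new = _eta_prior_loglik(prop, oinv, logdet, active)
    log_ratio = lp_obs_new + lp_pri_new - state.logp_obs - logp_pri
    accept = np.log(rng.random(n)) < log_ratio
    state.eta[accept] = prop[accept]
    state.logp_obs[accept] = lp_obs_new[accept]
    logp_pri[accept] = lp_pri_new[accept]
    state.step_full *= np.exp(adapt * (accept.astype(float) - target_accept))
    np.clip(state.step_full, 1e-3, 10.0, out=state.step_full)
    state.n_accept += int(accept.sum())
    state.n_propose += n

    # componentwise sweep
    sds = np.sqrt(np.diag(omega))
    for i in range(d):
        if not active[i]:
            continue
        prop = state.eta.copy()
        prop[:, i] = state.eta[:, i] + state.step_comp[:, i] * sds[i] * rng.standard_normal(n)
        lp_obs_new = problem.obs_loglik(phi_of(prop), rows, a, b)
        lp_pri_new = _eta_prior_loglik(prop, oinv, logdet, active)
        log_ratio = lp_obs_new + lp_pri_new - state.logp_obs - logp_pri
        accept = np.log(rng.random(n)) < log_ratio
        state.eta[accept] = prop[accept]
        state.logp_obs[accept] = lp_obs_new[accept]
        logp_pri[accept] = lp_pri_new[accept]
        state.step_comp[:, i] *= np.exp(adapt * (accept.astype(float) - target_accept))
        state.n_accept += int(accept.sum())
        state.n_propose += n
    np.clip(state.step_comp, 1e-3, 10.0, out=state.step_comp)


def mcmc_sample_eta(
    subject,
    theta: FixedEffects,
    spec: ModelSpec,
    omega: np.ndarray | RandomEffectSpec,
    err: ErrorParams,
    n_transitions: int,
    seed,
    cov_ref: CovariateVector | None = None,
    burn_in: int = 0,
) -> np.ndarray:
    """MH chain targeting p(eta | subject data); returns (n_transitions, 6).

    Each transition is one full-vector proposal plus a componentwise sweep.
    Raises if nothing is ever accepted (pathological proposal scales).
    """
    from .datasets import Dataset

    if isinstance(omega, RandomEffectSpec):
        omega = build_omega(omega)
    ds = Dataset(subjects=[subject])
    if cov_ref is None:
        cov_ref = subject.covariates
    problem = build_problem(ds, spec, cov_ref)
    d = problem.d
    xi = np.concatenate(
        [
            np.log([theta.pop[nm] for nm in PARAM_NAMES]),
            [theta.beta[link] for link in spec.links],
        ]
    )
    a = np.array([err.a])
    b = np.array([err.b])
    rng = np.random.default_rng(seed)
    state = MHState.initial(1, d)
    draws = np.empty((n_transitions, d))
    for k in range(burn_in + n_transitions):
        mh_transition(problem, state, omega, xi, a, b, rng)
        if k >= burn_in:
            draws[k - burn_in] = state.eta[0]
    if state.n_accept == 0:
        raise RuntimeError(
            "MH chain accepted no proposals; proposal scales are pathological"
        )
    return draws


# ---------------------------------------------------------------------------
# Importance sampling of the marginal log-likelihood
# ---------------------------------------------------------------------------

def _t_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray, df: float) -> np.ndarray:
    """Multivariate-t log-density for rows of x (k dimensions)."""
    k = mean.size
    diff = x - mean
    w = np.linalg.solve(chol, diff.T).T
    quad = np.sum(w**2, axis=1)
    logdet = np.sum(np.log(np.diag(chol)))
    return (
        gammaln((df + k) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * k * math.log(df * math.pi)
        - logdet
        - 0.5 * (df + k) * np.log1p(quad / df)
    )


def _t_rvs(mean: np.ndarray, chol: np.ndarray, df: float, size: int, rng) -> np.ndarray:
    k = mean.size
    z = rng.standard_normal((size, k)) @ chol.T
    g = rng.chisquare(df, size=size) / df
    return mean + z / np.sqrt(g)[:, None]


def is_loglik(
    problem: NLMEProblem,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    cond_mean: np.ndarray,
    cond_cov: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    df: float = 4.0,
    return_per_subject: bool = False,
    fixed_draws: np.ndarray | None = None,
):
    """Importance-sampling estimate of the marginal log-likelihood.

    The proposal for subject j is a multivariate t (df heavier-tailed than
    the Gaussian conditional) centered on the conditional mean with the
    conditional covariance. Returns (loglik, mc_se) or per-subject arrays.
    """
    n, d = cond_mean.shape
    active = np.sqrt(np.diag(omega)) > 0
    k = int(active.sum())
    oinv, logdet = prior_terms(omega, active)
    mean_phi = np.einsum("ndq,q->nd", problem.design, xi)

    ll = np.zeros(n)
    se2 = np.zeros(n)
    for j in range(n):
        cov_j = cond_cov[j][np.ix_(active, active)] + 1e-10 * np.eye(k)
        try:
            chol = np.linalg.cholesky(cov_j)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"degenerate IS proposal for subject {j}") from exc
        m_j = cond_mean[j, active]
        if fixed_draws is None:
            draws_a = _t_rvs(m_j, chol, df, n_samples, rng)
        else:
            draws_a = fixed_draws[j]
        n_draws = draws_a.shape[0]
        logq = _t_logpdf(draws_a, m_j, chol, df)
        eta = np.zeros((n_draws, d))
        eta[:, active] = draws_a
        phi = mean_phi[j] + eta
        rows = np.full(n_draws, j)
        lp = problem.obs_loglik(phi, rows, a, b) + _eta_prior_loglik(eta, oinv, logdet, active)
        logw = lp - logq
        m = logw.max()
        w = np.exp(logw - m)
        wbar = w.mean()
        ll[j] = m + math.log(wbar)
        se2[j] = w.var(ddof=1) / (n_draws * wbar**2)
    if return_per_subject:
        return ll, se2
    return float(ll.sum()), float(math.sqrt(se2.sum()))


def conditional_moments(
    problem: NLMEProblem,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 300,
    burn: int = 100,
    state: "MHState | None" = None,
) -> tuple[np.ndarray, np.ndarray, "MHState"]:
    """Per-subject conditional mean and covariance of eta by MCMC."""
    n, d = problem.n_subjects, problem.d
    if state is None:
        state = MHState.initial(n, d)
    s1 = np.zeros((n, d))
    s2 = np.zeros((n, d, d))
    kept = 0
    for k in range(n_iter):
        mh_transition(problem, state, omega, xi, a, b, rng)
        if k >= burn:
            s1 += state.eta
            s2 += state.eta[:, :, None] * state.eta[:, None, :]
            kept += 1
    mean = s1 / kept
    cov = s2 / kept - mean[:, :, None] * mean[:, None, :]
    cov += 1e-10 * np.eye(d)
    return mean, cov, state


def draw_is_proposal(
    cond_mean: np.ndarray,
    cond_cov: np.ndarray,
    active: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    df: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed heavy-tailed IS draws per subject: (draws (N,M,k), logq (N,M))."""
    n = cond_mean.shape[0]
    k = int(active.sum())
    draws = np.empty((n, n_samples, k))
    logq = np.empty((n, n_samples))
    for j in range(n):
        cov_j = cond_cov[j][np.ix_(active, active)] + 1e-10 * np.eye(k)
        chol = np.linalg.cholesky(cov_j)
        m_j = cond_mean[j, active]
        draws[j] = _t_rvs(m_j, chol, df, n_samples, rng)
        logq[j] = _t_logpdf(draws[j], m_j, chol, df)
    return draws, logq


def is_loglik_fixed(
    problem: NLMEProblem,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    draws: np.ndarray,
    logq: np.ndarray,
    active: np.ndarray,
) -> np.ndarray:
    """Per-subject IS log-likelihood with *fixed* proposal draws.

    Fully vectorized over subjects and draws; with common random numbers
    this makes the IS estimate a smooth deterministic function of the
    parameters, suitable for finite differences and quasi-Newton ascent.
    """
    n, m, k = draws.shape
    d = problem.d
    oinv, logdet = prior_terms(omega, active)
    eta = np.zeros((n, m, d))
    eta[:, :, active] = draws
    mean_phi = np.einsum("ndq,q->nd", problem.design, xi)
    phi = (mean_phi[:, None, :] + eta).reshape(n * m, d)
    rows = np.repeat(np.arange(n), m)
    ll_obs = problem.obs_loglik(phi, rows, a, b).reshape(n, m)
    lp = ll_obs + _eta_prior_loglik(eta.reshape(n * m, d), oinv, logdet, active).reshape(n, m)
    logw = lp - logq
    return logsumexp(logw, axis=1) - math.log(m)
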