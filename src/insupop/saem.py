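"""Stochastic-approximation EM (SAEM) with an MCMC E-step.

The complete-data model is linear in the latent log parameters:

    phi_j = A_j xi + eta_j,    eta_j ~ N(0, Omega),
    z_jk  = f(phi_j, t_jk) + sqrt(a_s² + b_s² f²) eps,

where ``A_j`` holds an identity block (log population values) plus one
column per covariate link (centered covariate value), so the M-step for
``xi`` is generalized least squares on the stochastically-approximated
sufficient statistics, and the Omega M-step is the structured projection of
the smoothed residual covariance. A log-normal prior on the population
distribution volume enters the xi update as a ridge term. The combined
error model is not exponential-family in (a, b); those are re-optimized
numerically each iteration on the current simulated residuals and smoothed
with the SAEM step size.

Schedule: an exploration phase with step size 1 (and simulated-annealing
floors that keep variances from collapsing early), then a smoothing phase
with step size k^(-0.7).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import PARAM_NAMES, ErrorParams
from .population import (
    CovariateVector,
    FixedEffects,
    ModelSpec,
    RandomEffectSpec,
)
from .likelihood import (
    MHState,
    NLMEProblem,
    build_problem,
    mh_transition,
    prior_terms,
    _eta_prior_loglik,
)

__all__ = ["FitConfig", "FitResult", "SAEMDivergenceError", "saem_fit"]

logger = logging.getLogger(__name__)

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

_VAR_FLOOR = 1e-8
_ERR_A2_FLOOR = 1e-12
_ERR_B2_FLOOR = 1e-12


class SAEMDivergenceError(RuntimeError):
    """Raised when SAEM statistics become non-finite; carries the trace."""

    def __init__(self, message: str, trace: pd.DataFrame | None = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class FitConfig:
    """Tuning knobs of the SAEM run.

    Defaults follow common SAEM practice: 300 exploration + 200 smoothing
    iterations, step size 1 then (k - K_expl)^(-0.7); one full-vector MH
    proposal plus one componentwise sweep per subject per iteration; a
    log-normal prior on VI_pop (location 0.126 L/kg, log-SD 0.1) improving
    its a-posteriori identifiability.
    """

    n_exploration: int = 300
    n_smoothing: int = 200
    step_exponent: float = 0.7
    mh_per_iteration: int = 1
    seed: int = 12345
    init_pop: dict[str, float] = field(
        default_factory=lambda: {
            "tau": 10.0,
            "VI": 0.126,
            "alpha": 0.01,
            "ka1": 0.001,
            "ka2": 0.01,
            "ke": 0.1,
        }
    )
    init_omega: float = 0.1
    init_error: tuple[float, float] = (1.0, 0.1)
    vi_prior: tuple[float, float] | None = (0.126, 0.1)  # (location L/kg, log-SD)
    annealing: bool = True
    anneal_factor: float = 0.95
    error_model: str = "combined"
    n_posterior: int = 400
    posterior_burn: int = 100
    ebe_method: str = "map"  # "map" | "mean"
    refine_rounds: int = 16      # 0 disables the penalized-likelihood polish
    refine_samples: int = 128
    refine_maxiter: int = 15

    def __post_init__(self) -> None:
        if self.n_exploration <= 0 or self.n_smoothing <= 0:
            raise ValueError("iteration counts must be positive")
        if not 0 < self.step_exponent <= 1:
            raise ValueError("step_exponent must lie in (0, 1]")


@dataclass
class LatentStructure:
    """Engine-level description of the latent mean/covariance model."""

    d: int
    corr_pairs: tuple[tuple[int, int], ...] = ()
    # Gaussian priors on components of xi: (index, location, sd)
    xi_priors: tuple[tuple[int, float, float], ...] = ()


@dataclass
class EngineResult:
    xi: np.ndarray
    omega: np.ndarray
    a: np.ndarray
    b: np.ndarray
    trace: pd.DataFrame
    state: MHState


def _project_omega(
    omega_full: np.ndarray,
    pairs: tuple[tuple[int, int], ...],
    var_prev: np.ndarray | None,
    anneal: float | None,
) -> np.ndarray:
    """Project a full covariance onto the declared sparsity pattern."""
    omega_full = 0.5 * (omega_full + omega_full.T)
    var_full = np.clip(np.diag(omega_full), _VAR_FLOOR, None)
    var = var_full.copy()
    if anneal is not None and var_prev is not None:
        var = np.maximum(var, anneal * var_prev)
    out = np.diag(var)
    for i, j in pairs:
        rho = omega_full[i, j] / math.sqrt(var_full[i] * var_full[j])
        rho = float(np.clip(rho, -0.98, 0.98))
        out[i, j] = out[j, i] = rho * math.sqrt(var[i] * var[j])
    # guard PSD: shrink off-diagonal entries until the smallest eigenvalue is safe
    for _ in range(60):
        if np.linalg.eigvalsh(out)[0] >= 1e-10:
            break
        off = out - np.diag(np.diag(out))
        out = np.diag(np.diag(out)) + 0.9 * off
    return out


def _update_error(
    problem: NLMEProblem,
    y: np.ndarray,
    a2: np.ndarray,
    b2: np.ndarray,
    gamma: float,
    model: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study error-parameter M-step on the current simulated residuals."""
    z = problem.obs
    m = problem.mask
    for s in range(len(problem.study_labels)):
        rows = problem.study_idx == s
        msk = m[rows]
        if not msk.any():
            continue
        ys = y[rows][msk]
        rs = z[rows][msk] - ys
        r2 = rs**2
        if model == "constant":
            a2_new, b2_new = float(r2.mean()), 0.0
        elif model == "proportional":
            yy = np.clip(ys, 1e-12, None) ** 2
            a2_new, b2_new = 0.0, float((r2 / yy).mean())
        else:  # combined

            def nll(logab):
                v = math.exp(2 * logab[0]) + math.exp(2 * logab[1]) * ys**2
                return float(np.sum(np.log(v) + r2 / v))

            x0 = 0.5 * np.log([max(a2[s], 1e-10), max(b2[s], 1e-10)])
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-6})
            a2_new = math.exp(2 * res.x[0])
            b2_new = math.exp(2 * res.x[1])
        a2[s] += gamma * (a2_new - a2[s])
        b2[s] += gamma * (b2_new - b2[s])
    np.clip(a2, _ERR_A2_FLOOR, None, out=a2)
    np.clip(b2, _ERR_B2_FLOOR, None, out=b2)
    return a2, b2


def run_saem(
    problem: NLMEProblem,
    structure: LatentStructure,
    config: FitConfig,
    xi0: np.ndarray,
    omega0: np.ndarray,
    a0: np.ndarray,
    b0: np.ndarray,
    rng: np.random.Generator,
) -> EngineResult:
    """Run SAEM on a stacked problem; generic in the structural predictor."""
    n, d = problem.n_subjects, structure.d
    xi = np.asarray(xi0, dtype=float).copy()
    omega = np.asarray(omega0, dtype=float).copy()
    a2 = np.asarray(a0, dtype=float) ** 2
    b2 = np.asarray(b0, dtype=float) ** 2

    state = MHState.initial(n, d)
    s1 = np.zeros((n, d))
    s2 = np.zeros((d, d))
    trace_rows = []
    n_iter = config.n_exploration + config.n_smoothing

    design = problem.design
    for k in range(n_iter):
        exploring = k < config.n_exploration
        gamma = 1.0 if exploring else (k - config.n_exploration + 1) ** (-config.step_exponent)

        a = np.sqrt(a2)
        b = np.sqrt(b2)
        for _ in range(config.mh_per_iteration):
            mh_transition(problem, state, omega, xi, a, b, rng)

        phi = np.einsum("ndq,q->nd", design, xi) + state.eta
        s1 += gamma * (phi - s1)
        s2 += gamma * (phi.T @ phi - s2)

        # error-parameter update on current simulated predictions
        y = problem.predict(phi, np.arange(n))
        a2, b2 = _update_error(problem, y, a2, b2, gamma, config.error_model)

        # GLS update of xi at the current Omega
        oinv = np.linalg.inv(omega + 1e-12 * np.eye(d))
        lhs = np.einsum("ndq,de,nef->qf", design, oinv, design)
        rhs = np.einsum("ndq,de,ne->q", design, oinv, s1)
        for idx, loc, sd in structure.xi_priors:
            lhs[idx, idx] += 1.0 / sd**2
            rhs[idx] += loc / sd**2
        xi = np.linalg.solve(lhs, rhs)

        # structured Omega update from the smoothed second moments
        mu = np.einsum("ndq,q->nd", design, xi)
        r = s2 - mu.T @ s1 - s1.T @ mu + mu.T @ mu
        omega = _project_omega(
            r / n,
            structure.corr_pairs,
            np.diag(omega),
            config.anneal_factor if (exploring and config.annealing) else None,
        )

        if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(omega))):
            raise SAEMDivergenceError(
                f"non-finite SAEM statistics at iteration {k}",
                trace=pd.DataFrame(trace_rows),
            )
        row = {"iteration": k, "gamma": gamma}
        row.update({f"xi_{i}": xi[i] for i in range(len(xi))})
        row.update({f"omega_{i}": math.sqrt(omega[i, i]) for i in range(d)})
        row.update({f"a_{s}": math.sqrt(a2[s]) for s in range(len(a2))})
        row.update({f"b_{s}": math.sqrt(b2[s]) for s in range(len(b2))})
        trace_rows.append(row)

    return EngineResult(
        xi=xi,
        omega=omega,
        a=np.sqrt(a2),
        b=np.sqrt(b2),
        trace=pd.DataFrame(trace_rows),
        state=state,
    )


# ---------------------------------------------------------------------------
# Penalized-likelihood refinement
# ---------------------------------------------------------------------------

def _pack_zeta(xi, omega, a, b, pairs):
    sd = np.sqrt(np.diag(omega))
    rho = [omega[i, j] / (sd[i] * sd[j]) for i, j in pairs]
    ab = np.empty(2 * len(a))
    ab[0::2] = a
    ab[1::2] = b
    return np.concatenate([xi, np.log(sd), np.arctanh(np.clip(rho, -0.98, 0.98)), np.log(ab)])


def _unpack_zeta(zeta, n_xi, d, pairs, n_stud):
    xi = zeta[:n_xi]
    sd = np.exp(zeta[n_xi : n_xi + d])
    rho = np.tanh(zeta[n_xi + d : n_xi + d + len(pairs)])
    ab = np.exp(zeta[n_xi + d + len(pairs) :])
    omega = np.diag(sd**2)
    for r, (i, j) in zip(rho, pairs):
        omega[i, j] = omega[j, i] = r * sd[i] * sd[j]
    return xi, omega, ab[0::2], ab[1::2]


def refine_penalized_mle(
    problem: NLMEProblem,
    structure: LatentStructure,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    state: MHState | None = None,
    n_rounds: int = 12,
    n_samples: int = 128,
    maxiter: int = 15,
    xtol: float = 5e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, MHState]:
    """Polish SAEM output by direct ascent of the penalized marginal likelihood.

    The marginal log-likelihood is estimated by importance sampling with
    *fixed* heavy-tailed draws (common random numbers), making it a smooth
    deterministic function of the parameters, so quasi-Newton ascent makes
    progress along weakly-identified ridges (the distribution-volume /
    elimination trade-off) where stochastic approximation drifts slowly.
    Because fixed draws are only trustworthy near their conditional
    proposal, the ascent runs in short recentered rounds: refresh the
    conditional moments at the current parameters, optimize the fixed
    effects and Omega parameters within the trust region, update the error
    parameters by their EM step, repeat until the step stalls.
    """
    from .likelihood import conditional_moments, draw_is_proposal, is_loglik_fixed

    pairs = structure.corr_pairs
    n = problem.n_subjects

    def omega_em_step(cm, cc):
        # M-step residual is exactly eta: Omega = (1/N) sum_j E[eta_j eta_j']
        second = cc.mean(axis=0) + (cm[:, :, None] * cm[:, None, :]).mean(axis=0)
        return _project_omega(second, pairs, None, None)

    def error_em_pass(n_mh: int):
        nonlocal a, b
        a2, b2 = a**2, b**2
        for k in range(n_mh):
            mh_transition(problem, state, omega, xi, a, b, rng)
            if k >= n_mh // 3 and k % 10 == 0:
                phi = np.einsum("ndq,q->nd", problem.design, xi) + state.eta
                y = problem.predict(phi, np.arange(n))
                a2, b2 = _update_error(problem, y, a2, b2, 0.5, "combined")
                a, b = np.sqrt(a2), np.sqrt(b2)

    def xi_rounds(max_rounds: int):
        nonlocal xi, omega, state
        for _ in range(max_rounds):
            cond_mean, cond_cov, state = conditional_moments(
                problem, xi, omega, a, b, rng, n_iter=120, burn=40, state=state
            )
            omega = omega_em_step(cond_mean, cond_cov)
            active = np.sqrt(np.diag(omega)) > 0
            draws, logq = draw_is_proposal(cond_mean, cond_cov, active, n_samples, rng)

            def neg_penalized(xi_z):
                try:
                    ll = is_loglik_fixed(
                        problem, xi_z, omega, a, b, draws, logq, active
                    ).sum()
                except np.linalg.LinAlgError:
                    return 1e10
                for idx, loc, sd in structure.xi_priors:
                    ll -= 0.5 * ((xi_z[idx] - loc) / sd) ** 2
                return -ll if np.isfinite(ll) else 1e10

            res = optimize.minimize(
                neg_penalized, xi, method="L-BFGS-B",
                options={"maxiter": maxiter, "maxcor": 25},
            )
            step = float(np.max(np.abs(res.x - xi)))
            xi = res.x
            error_em_pass(50)
            if step < xtol:
                break

    def omega_polish(max_iter: int):
        # the Omega EM map converges linearly; iterate it to its fixed
        # point at fixed xi (the correlated block is the slow component)
        nonlocal omega, state
        for k in range(max_iter):
            cond_mean, cond_cov, state = conditional_moments(
                problem, xi, omega, a, b, rng, n_iter=130, burn=40, state=state
            )
            omega_new = omega_em_step(cond_mean, cond_cov)
            delta = np.max(np.abs(omega_new - omega) / np.sqrt(
                np.outer(np.diag(omega_new), np.diag(omega_new)) + 1e-12
            ))
            omega = omega_new
            error_em_pass(20)
            if k >= 5 and delta < 0.01:
                break

    # alternate: fixed-effect ascent, then Omega to its fixed point, then a
    # short re-ascent of xi under the settled covariance
    xi_rounds(n_rounds)
    omega_polish(24)
    xi_rounds(max(2, n_rounds // 4))
    omega_polish(10)
    return xi, omega, a, b, state


def posterior_pass(
    problem: NLMEProblem,
    config: FitConfig,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    state: MHState | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, MHState]:
    """Final conditional moments and per-subject MAP random effects."""
    from .likelihood import conditional_moments

    cond_mean, cond_cov, state = conditional_moments(
        problem, xi, omega, a, b, rng,
        n_iter=config.n_posterior, burn=config.posterior_burn, state=state,
    )
    eta_map = _map_eta(problem, xi, omega, a, b, cond_mean)
    return cond_mean, cond_cov, eta_map, state


def _map_eta(
    problem: NLMEProblem,
    xi: np.ndarray,
    omega: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    start: np.ndarray,
) -> np.ndarray:
    """Per-subject conditional mode of eta (empirical Bayes estimates)."""
    n, d = start.shape
    active = np.sqrt(np.diag(omega)) > 1e-6
    oinv, logdet = prior_terms(omega, active)
    mean_phi = np.einsum("ndq,q->nd", problem.design, xi)
    out = np.zeros((n, d))
    for j in range(n):
        row = np.array([j])

        def neg_logpost(e_active):
            eta = np.zeros((1, d))
            eta[0, active] = e_active
            ll = problem.obs_loglik(mean_phi[row] + eta, row, a, b)[0]
            lp = _eta_prior_loglik(eta, oinv, logdet, active)[0]
            return -(ll + lp)

        res = optimize.minimize(
            neg_logpost, start[j, active], method="Nelder-Mead",
            options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-7},
        )
        out[j, active] = res.x
    return out


# ---------------------------------------------------------------------------
# Insulin-model front end
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Everything a fitted model reports.

    ``theta``/``random_effects``/``error`` are the population estimates;
    ``eta_map``/``eta_mean`` the per-subject empirical Bayes estimates (the
    conditional mode is the default EBE, the conditional mean an option);
    ``individual_params`` the natural-scale kinetic parameters implied by
    the EBEs. Likelihood and precision fields are filled by
    :func:`~insupop.inference.loglik_importance_sampling` and
    :func:`~insupop.inference.fim_and_rse`.
    """

    spec: ModelSpec
    config: FitConfig
    theta: FixedEffects
    random_effects: RandomEffectSpec
    error: dict[str, ErrorParams]
    cov_ref: CovariateVector
    subject_ids: tuple[str, ...]
    eta_map: pd.DataFrame
    eta_mean: pd.DataFrame
    cond_cov: np.ndarray
    individual_params: pd.DataFrame
    trace: pd.DataFrame
    accept_rate: float
    loglik: float | None = None
    loglik_se: float | None = None
    fim: np.ndarray | None = None
    cov_matrix: pd.DataFrame | None = None
    rse: pd.Series | None = None
    _problem: NLMEProblem | None = field(default=None, repr=False)
    _dataset: object | None = field(default=None, repr=False)

    # -- reporting -------------------------------------------------------

    def parameter_labels(self) -> list[str]:
        labels = [f"{p}_pop" for p in PARAM_NAMES]
        labels += [link.label for link in self.spec.links]
        labels += [f"omega_{p}" for p in PARAM_NAMES]
        labels += [f"rho_{p1},{p2}" for p1, p2 in self.spec.corr_pairs]
        for s in sorted(self.error):
            labels += [f"a_{s}", f"b_{s}"]
        return labels

    def parameter_values(self) -> pd.Series:
        vals = [self.theta.pop[p] for p in PARAM_NAMES]
        vals += [self.theta.beta[link] for link in self.spec.links]
        vals += list(self.random_effects.omega)
        vals += [self.random_effects.rho[pair] for pair in self.spec.corr_pairs]
        for s in sorted(self.error):
            vals += [self.error[s].a, self.error[s].b]
        return pd.Series(vals, index=self.parameter_labels(), name="estimate")

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / unit / RSE% table in the conventional reporting layout."""
        units = {"tau_pop": "min", "VI_pop": "L/kg"}
        for p in ("alpha", "ka1", "ka2", "ke"):
            units[f"{p}_pop"] = "min-1"
        beta_units = {"BMI": "m2/kg", "BW": "1/kg", "BH": "1/cm", "BSA": "1/m2"}
        for link in self.spec.links:
            units[link.label] = "dimensionless" if link.log else beta_units.get(
                link.covariate, ""
            )
        est = self.parameter_values()
        tab = pd.DataFrame({"estimate": est})
        tab["unit"] = [
            units.get(lbl, "uU/mL" if lbl.startswith("a_") else "dimensionless")
            for lbl in tab.index
        ]
        tab["rse_percent"] = self.rse.reindex(tab.index) if self.rse is not None else np.nan
        return tab

    def to_json(self, path) -> None:
        self.parameter_table().reset_index(names="parameter").to_json(
            path, orient="records", indent=2
        )

    def ebes_to_csv(self, path) -> None:
        out = self.individual_params.copy()
        eta = self.eta_map if self.config.ebe_method == "map" else self.eta_mean
        for p in PARAM_NAMES:
            out[f"eta_{p}"] = eta[p]
        out.to_csv(path)

    # -- model predictions ----------------------------------------------

    def individual_predictions(self) -> dict[str, np.ndarray]:
        """EBE-based predicted concentrations on each subject's time grid."""
        problem = self._problem
        eta = (self.eta_map if self.config.ebe_method == "map" else self.eta_mean).to_numpy()
        xi = self._xi()
        phi = np.einsum("ndq,q->nd", problem.design, xi) + eta
        y = problem.predict(phi, np.arange(problem.n_subjects))
        return {
            sid: y[j][problem.mask[j]] for j, sid in enumerate(self.subject_ids)
        }

    def iwres_by_subject(self) -> dict[str, np.ndarray]:
        """Individual weighted residuals per subject at the EBEs."""
        problem = self._problem
        preds = self.individual_predictions()
        out = {}
        for j, sid in enumerate(self.subject_ids):
            z = problem.obs[j][problem.mask[j]]
            s = problem.study_labels[problem.study_idx[j]]
            e = self.error[s]
            y = preds[sid]
            out[sid] = (z - y) / np.sqrt(e.a**2 + e.b**2 * y**2)
        return out

    def _xi(self) -> np.ndarray:
        return np.concatenate(
            [
                np.log([self.theta.pop[p] for p in PARAM_NAMES]),
                [self.theta.beta[link] for link in self.spec.links],
            ]
        )


def saem_fit(dataset, spec: ModelSpec, config: FitConfig | None = None) -> FitResult:
    """Fit the insulin population model by SAEM.

    ``dataset`` needs at least two subjects with two observations each;
    ``spec`` is one of :func:`~insupop.population.candidate_models` (or any
    custom :class:`~insupop.population.ModelSpec`).
    """
    config = config or FitConfig()
    if dataset.n_subjects < 2 or any(s.n_obs < 2 for s in dataset.subjects):
        raise ValueError("need >= 2 subjects with >= 2 observations each")

    cov_ref = dataset.mean_covariates()
    problem = build_problem(dataset, spec, cov_ref)
    problem.error_model = config.error_model
    d = len(PARAM_NAMES)

    pairs = tuple(
        (_PARAM_INDEX[p1], _PARAM_INDEX[p2]) for p1, p2 in spec.corr_pairs
    )
    priors = ()
    if config.vi_prior is not None:
        loc, sd = config.vi_prior
        priors = ((_PARAM_INDEX["VI"], math.log(loc), sd),)
    structure = LatentStructure(d=d, corr_pairs=pairs, xi_priors=priors)

    xi0 = np.concatenate(
        [np.log([config.init_pop[p] for p in PARAM_NAMES]), np.zeros(spec.n_beta)]
    )
    omega0 = np.eye(d) * config.init_omega**2
    n_stud = len(problem.study_labels)
    a0 = np.full(n_stud, config.init_error[0])
    b0 = np.full(n_stud, config.init_error[1])
    rng = np.random.default_rng(config.seed)

    res = run_saem(problem, structure, config, xi0, omega0, a0, b0, rng)
    xi_hat, omega_hat, a_hat, b_hat, state = res.xi, res.omega, res.a, res.b, res.state
    if config.refine_rounds > 0:
        xi_hat, omega_hat, a_hat, b_hat, state = refine_penalized_mle(
            problem, structure, xi_hat, omega_hat, a_hat, b_hat, rng,
            state=state, n_rounds=config.refine_rounds,
            n_samples=config.refine_samples, maxiter=config.refine_maxiter,
        )
    cond_mean, cond_cov, eta_map_arr, state = posterior_pass(
        problem, config, xi_hat, omega_hat, a_hat, b_hat, rng, state
    )
    accept_rate = state.n_accept / max(state.n_propose, 1)
    logger.info("SAEM finished; overall MH acceptance %.1f%%", 100 * accept_rate)

    pop = dict(zip(PARAM_NAMES, np.exp(xi_hat[:d])))
    beta = {link: float(xi_hat[d + i]) for i, link in enumerate(spec.links)}
    theta = FixedEffects(pop=pop, beta=beta)
    omega_sd = np.sqrt(np.diag(omega_hat))
    rho = {}
    for p1, p2 in spec.corr_pairs:
        i, j = _PARAM_INDEX[p1], _PARAM_INDEX[p2]
        rho[(p1, p2)] = float(omega_hat[i, j] / (omega_sd[i] * omega_sd[j]))
    respec = RandomEffectSpec(omega=tuple(omega_sd), rho=rho)
    error = {
        lab: ErrorParams(a=float(a_hat[i]), b=float(b_hat[i]), study=lab)
        for i, lab in enumerate(problem.study_labels)
    }

    ids = list(problem.subject_ids)
    eta_map = pd.DataFrame(eta_map_arr, index=ids, columns=list(PARAM_NAMES))
    eta_mean = pd.DataFrame(cond_mean, index=ids, columns=list(PARAM_NAMES))
    eta_for_params = eta_map_arr if config.ebe_method == "map" else cond_mean
    phi = np.einsum("ndq,q->nd", problem.design, xi_hat) + eta_for_params
    indiv = pd.DataFrame(np.exp(phi[:, :d]), index=ids, columns=list(PARAM_NAMES))
    indiv.index.name = "ID"

    return FitResult(
        spec=spec,
        config=config,
        theta=theta,
        random_effects=respec,
        error=error,
        cov_ref=cov_ref,
        subject_ids=problem.subject_ids,
        eta_map=eta_map,
        eta_mean=eta_mean,
        cond_cov=cond_cov,
        individual_params=indiv,
        trace=res.trace,
        accept_rate=accept_rate,
        _problem=problem,
        _dataset=dataset,
    )
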