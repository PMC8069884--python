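"""Likelihood machinery against conjugate closed forms, plus criteria.

The linear-Gaussian toy (identity structural function, constant error)
makes every quantity available in closed form: the conditional posterior of
the random effect, the marginal likelihood, and the maximum-likelihood
estimates. The same engine code paths (MH kernel, SAEM loop, importance
sampling) that fit the insulin model are exercised on the toy.
"""

import math

import numpy as np
import pytest
from scipy import optimize, stats

import insupop as ip
from insupop.likelihood import (
    MHState,
    NLMEProblem,
    is_loglik,
    mh_transition,
    conditional_moments,
)
from insupop.saem import FitConfig, LatentStructure, run_saem
from insupop.inference import bicc, count_parameters


def make_toy_problem(n_subjects=40, n_obs=5, mu=1.0, omega=0.5, sigma=0.2, seed=0):
    """One-way random-effects toy: z_jk = phi_j + eps, phi_j ~ N(mu, omega^2)."""
    rng = np.random.default_rng(seed)
    phi = mu + omega * rng.standard_normal(n_subjects)
    z = phi[:, None] + sigma * rng.standard_normal((n_subjects, n_obs))

    def predict(phi_rows, rows):
        return np.repeat(phi_rows, n_obs, axis=1)

    problem = NLMEProblem(
        times=np.zeros((n_subjects, n_obs)),
        obs=z,
        mask=np.ones((n_subjects, n_obs), dtype=bool),
        study_idx=np.zeros(n_subjects, dtype=int),
        study_labels=("toy",),
        design=np.ones((n_subjects, 1, 1)),
        predict=predict,
        d=1,
        q=1,
        error_model="constant",
    )
    return problem, z, phi


def toy_marginal_loglik(z, mu, omega, sigma):
    """Exact marginal log-likelihood of the toy (conjugate closed form)."""
    n, k = z.shape
    cov = sigma**2 * np.eye(k) + omega**2 * np.ones((k, k))
    return float(
        sum(stats.multivariate_normal.logpdf(z[j], mean=np.full(k, mu), cov=cov)
            for j in range(n))
    )


class TestConditionalLogdensity:
    def test_matches_hand_computed_sum(self, reference_model):
        theta, spec, respec = reference_model
        cov = ip.derive_covariates(BW=74, BH=175, AGE=42)
        subj = ip.Subject(
            id="s", study="study2",
            times=np.array([30.0, 60.0, 120.0]),
            conc=np.array([40.0, 65.0, 50.0]),
            dose=ip.DoseEvent(amount=0.2, per_kg=True),
            covariates=cov,
        )
        err = ip.ErrorParams(a=2.33, b=0.0516)
        eta = np.array([0.1, -0.1, 0.2, 0.0, 0.1, -0.2])
        got = ip.conditional_logdensity(subj, eta, theta, spec, respec, err, cov_ref=cov)
        # independent arithmetic: structural solve + explicit Gaussian terms
        params = ip.individual_params(theta, spec, cov, cov, eta)
        y = ip.solve_pk(params, subj.dose, subj.times, 74.0)
        sd = np.sqrt(err.a**2 + err.b**2 * y**2)
        ll_obs = np.sum(stats.norm.logpdf(subj.conc, loc=y, scale=sd))
        omega = ip.build_omega(respec)
        ll_pri = stats.multivariate_normal.logpdf(eta, mean=np.zeros(6), cov=omega)
        assert got == pytest.approx(ll_obs + ll_pri, rel=1e-10)

    def test_no_observations_reduces_to_prior(self, reference_model):
        theta, spec, respec = reference_model
        cov = ip.derive_covariates(BW=74, BH=175, AGE=42)
        subj = ip.Subject(
            id="s", study="study1", times=np.array([]), conc=np.array([]),
            dose=ip.DoseEvent(amount=12.0), covariates=cov,
        )
        eta = np.zeros(6)
        got = ip.conditional_logdensity(
            subj, eta, theta, spec, respec, ip.ErrorParams(a=2.0, b=0.05), cov_ref=cov
        )
        omega = ip.build_omega(respec)
        assert got == pytest.approx(
            stats.multivariate_normal.logpdf(eta, np.zeros(6), omega), rel=1e-10
        )

    def test_density_decreases_with_misfit(self, reference_model):
        theta, spec, respec = reference_model
        cov = ip.derive_covariates(BW=74, BH=175, AGE=42)
        err = ip.ErrorParams(a=2.33, b=0.0516)
        eta = np.zeros(6)
        base = ip.individual_params(theta, spec, cov, cov, eta)
        y = ip.solve_pk(base, ip.DoseEvent(amount=12.0), np.array([60.0, 120.0]), 74.0)
        vals = []
        for shift in (0.0, 5.0, 15.0):
            subj = ip.Subject(
                id="s", study="study1", times=np.array([60.0, 120.0]),
                conc=y + shift, dose=ip.DoseEvent(amount=12.0), covariates=cov,
            )
            vals.append(
                ip.conditional_logdensity(subj, eta, theta, spec, respec, err, cov_ref=cov)
            )
        assert vals[0] > vals[1] > vals[2]


class TestMHChainConjugate:
    def test_chain_moments_match_gaussian_posterior(self):
        problem, z, _ = make_toy_problem(seed=3)
        mu, omega, sigma = 1.0, 0.5, 0.2
        k = z.shape[1]
        # conjugate posterior of eta_j = phi_j - mu
        post_var = 1.0 / (1.0 / omega**2 + k / sigma**2)
        post_mean = post_var * (k / sigma**2) * (z.mean(axis=1) - mu)

        rng = np.random.default_rng(0)
        st = MHState.initial(problem.n_subjects, 1)
        om = np.array([[omega**2]])
        a = np.array([sigma])
        b = np.array([0.0])
        xi = np.array([mu])
        draws = []
        for it in range(6000):
            mh_transition(problem, st, om, xi, a, b, rng)
            if it >= 1000:
                draws.append(st.eta[:, 0].copy())
        draws = np.asarray(draws)
        assert np.allclose(draws.mean(axis=0), post_mean, atol=4 * math.sqrt(post_var / 50))
        assert draws.var(axis=0).mean() == pytest.approx(post_var, rel=0.1)

    def test_no_observations_reproduces_prior(self):
        problem, z, _ = make_toy_problem(n_subjects=200, seed=5)
        problem.mask[:] = False  # remove all observations
        rng = np.random.default_rng(1)
        st = MHState.initial(problem.n_subjects, 1)
        om = np.array([[0.49]])
        draws = []
        for it in range(3000):
            mh_transition(problem, st, om, np.array([0.0]), np.array([1.0]), np.array([0.0]), rng)
            if it >= 500:
                draws.append(st.eta[:, 0].copy())
        draws = np.asarray(draws).ravel()
        assert draws.mean() == pytest.approx(0.0, abs=0.02)
        assert draws.var() == pytest.approx(0.49, rel=0.05)

    def test_same_seed_identical_chain(self, reference_model):
        theta, spec, respec = reference_model
        cov = ip.derive_covariates(BW=74, BH=175, AGE=42)
        subj = ip.Subject(
            id="s", study="study1",
            times=np.array([30.0, 60.0, 120.0]),
            conc=np.array([40.0, 65.0, 50.0]),
            dose=ip.DoseEvent(amount=12.0), covariates=cov,
        )
        err = ip.ErrorParams(a=1.96, b=0.0773)
        c1 = ip.mcmc_sample_eta(subj, theta, spec, respec, err, 50, seed=42)
        c2 = ip.mcmc_sample_eta(subj, theta, spec, respec, err, 50, seed=42)
        assert np.array_equal(c1, c2)
        assert c1.shape == (50, 6)


class TestSAEMLinearToy:
    def test_estimates_match_exact_mle(self):
        problem, z, _ = make_toy_problem(n_subjects=60, n_obs=8, seed=11)

        # oracle: direct numeric maximization of the exact marginal likelihood
        def neg(p):
            mu, lw, ls = p
            return -toy_marginal_loglik(z, mu, math.exp(lw), math.exp(ls))

        opt = optimize.minimize(neg, [0.5, math.log(0.3), math.log(0.3)], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        mu_mle, omega_mle, sigma_mle = opt.x[0], math.exp(opt.x[1]), math.exp(opt.x[2])

        cfg = FitConfig(
            n_exploration=150, n_smoothing=4000, mh_per_iteration=2,
            error_model="constant", annealing=True, seed=2,
        )
        structure = LatentStructure(d=1)
        res = run_saem(
            problem, structure, cfg,
            xi0=np.array([0.0]), omega0=np.array([[0.09]]),
            a0=np.array([1.0]), b0=np.array([0.0]),
            rng=np.random.default_rng(8),
        )
        assert res.xi[0] == pytest.approx(mu_mle, abs=1e-3)
        assert math.sqrt(res.omega[0, 0]) == pytest.approx(omega_mle, abs=5e-3)
        assert res.a[0] == pytest.approx(sigma_mle, abs=2e-3)

    def test_zero_variability_deterministic_limit(self):
        # all subjects share phi = mu and observations are exact
        n, k, mu = 20, 6, 1.3
        problem, _, _ = make_toy_problem(n_subjects=n, n_obs=k, mu=mu, omega=0.0, sigma=0.0, seed=4)
        cfg = FitConfig(n_exploration=80, n_smoothing=300, error_model="constant", seed=5)
        res = run_saem(
            problem, LatentStructure(d=1), cfg,
            xi0=np.array([0.0]), omega0=np.array([[0.04]]),
            a0=np.array([0.5]), b0=np.array([0.0]),
            rng=np.random.default_rng(3),
        )
        assert res.xi[0] == pytest.approx(mu, abs=1e-4)
        assert math.sqrt(res.omega[0, 0]) < 1e-2


class TestImportanceSampling:
    def _setup(self, seed=21):
        problem, z, _ = make_toy_problem(n_subjects=30, n_obs=5, seed=seed)
        mu, omega, sigma = 1.0, 0.5, 0.2
        rng = np.random.default_rng(0)
        cm, cc, _ = conditional_moments(
            problem, np.array([mu]), np.array([[omega**2]]),
            np.array([sigma]), np.array([0.0]), rng, n_iter=800, burn=200,
        )
        return problem, z, mu, omega, sigma, cm, cc

    def test_matches_closed_form_marginal(self):
        problem, z, mu, omega, sigma, cm, cc = self._setup()
        rng = np.random.default_rng(7)
        ll, se = is_loglik(
            problem, np.array([mu]), np.array([[omega**2]]),
            np.array([sigma]), np.array([0.0]), cm, cc, 10_000, rng,
        )
        exact = toy_marginal_loglik(z, mu, omega, sigma)
        assert ll == pytest.approx(exact, abs=3 * max(se, 1e-6))
        assert abs(ll - exact) < 0.5  # consistency: bias below MC noise scale

    def test_mc_se_scales_inverse_sqrt(self):
        problem, z, mu, omega, sigma, cm, cc = self._setup()
        ses = []
        for n_samp in (100, 1000, 10_000):
            rng = np.random.default_rng(17)
            _, se = is_loglik(
                problem, np.array([mu]), np.array([[omega**2]]),
                np.array([sigma]), np.array([0.0]), cm, cc, n_samp, rng,
            )
            ses.append(se)
        assert ses[0] > ses[1] > ses[2]
        assert ses[0] / ses[2] == pytest.approx(10.0, rel=0.5)

    def test_fixed_seed_reproducible(self, small_fit, small_trial):
        ll1, se1 = ip.loglik_importance_sampling(small_trial.dataset, small_fit, 500, seed=9)
        ll2, se2 = ip.loglik_importance_sampling(small_trial.dataset, small_fit, 500, seed=9)
        assert ll1 == ll2 and se1 == se2


class TestCriteria:
    def test_bicc_zero(self):
        assert bicc(0.0, 10, 100, 0, 0) == 0.0

    def test_bicc_arithmetic(self):
        val = bicc(-7000.0, 116, 3000, 10, 12)
        assert val == pytest.approx(14143.61, abs=0.01)

    def test_penalty_difference_one_extra_variability_parameter(self):
        # one extra covariate coefficient costs ln(N), not ln(ntot)
        models = ip.candidate_models()
        pr3, pf3, _ = count_parameters(models[3])
        pr11, pf11, _ = count_parameters(models[11])
        assert (pr11 - pr3, pf11 - pf3) == (1, 0)
        delta = bicc(-7000.0, 116, 3000, pr11, pf11) - bicc(-7000.0, 116, 3000, pr3, pf3)
        assert delta == pytest.approx(math.log(116))

    def test_parameter_counts_across_ledger(self):
        models = ip.candidate_models()
        totals = [count_parameters(models[i])[2] for i in range(1, 15)]
        assert totals == [18, 19, 21, 22, 22, 22, 22, 22, 22, 22, 22, 23, 23, 23]
        assert count_parameters(models[11])[:2] == (10, 12)
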