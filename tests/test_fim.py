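"""Fisher-information and RSE machinery.

The conjugate toy gives the information for the population mean in closed
form, N/(omega^2 + sigma^2/K); the score-outer-product estimator built on
common-random-number importance sampling must reproduce it. On a fitted
model the score and Hessian routes are two independent numeric estimates
of the same matrix and must broadly agree.
"""

import numpy as np
import pytest

import insupop as ip
from insupop.inference import fim_and_rse
from insupop.likelihood import conditional_moments, draw_is_proposal, is_loglik_fixed
from tests.test_inference import make_toy_problem


class TestScoreEstimatorClosedForm:
    def test_information_for_population_mean(self):
        n, k, mu, omega, sigma = 80, 6, 1.0, 0.5, 0.2
        problem, z, _ = make_toy_problem(n, k, mu, omega, sigma, seed=30)
        rng = np.random.default_rng(0)
        om = np.array([[omega**2]])
        a, b = np.array([sigma]), np.array([0.0])
        cm, cc, _ = conditional_moments(problem, np.array([mu]), om, a, b, rng,
                                        n_iter=600, burn=150)
        active = np.array([True])
        draws, logq = draw_is_proposal(cm, cc, active, 2000, rng)
        h = 1e-4
        lp = is_loglik_fixed(problem, np.array([mu + h]), om, a, b, draws, logq, active)
        lm = is_loglik_fixed(problem, np.array([mu - h]), om, a, b, draws, logq, active)
        scores = (lp - lm) / (2 * h)
        fim = float(np.sum(scores**2))
        # analytic per-subject marginal score: K (zbar - mu) / (sigma^2 + K omega^2)
        exact_scores = k * (z.mean(axis=1) - mu) / (sigma**2 + k * omega**2)
        assert np.corrcoef(scores, exact_scores)[0, 1] > 0.97
        assert fim == pytest.approx(float(np.sum(exact_scores**2)), rel=0.15)
        # and the expectation it estimates
        assert fim == pytest.approx(n / (omega**2 + sigma**2 / k), rel=0.35)

    def test_rse_shrinks_with_sample_size(self):
        # doubling the subjects roughly halves the variance of the mean
        fims = []
        for n in (40, 160):
            problem, z, _ = make_toy_problem(n, 6, 1.0, 0.5, 0.2, seed=31)
            rng = np.random.default_rng(1)
            om = np.array([[0.25]])
            a, b = np.array([0.2]), np.array([0.0])
            cm, cc, _ = conditional_moments(problem, np.array([1.0]), om, a, b, rng,
                                            n_iter=400, burn=100)
            draws, logq = draw_is_proposal(cm, cc, np.array([True]), 1000, rng)
            h = 1e-4
            lp = is_loglik_fixed(problem, np.array([1.0 + h]), om, a, b, draws, logq,
                                 np.array([True]))
            lm = is_loglik_fixed(problem, np.array([1.0 - h]), om, a, b, draws, logq,
                                 np.array([True]))
            fims.append(float(np.sum(((lp - lm) / (2 * h)) ** 2)))
        assert fims[1] / fims[0] == pytest.approx(4.0, rel=0.35)

    def test_score_and_hessian_routes_match_analytic_counterparts(self):
        # conjugate toy: the marginal Hessian for mu is the constant
        # K/(sigma^2 + K omega^2) per subject, and the realized score outer
        # product is available in closed form — each numeric route must
        # reproduce its own analytic counterpart
        n, k, mu, omega, sigma = 60, 6, 1.0, 0.5, 0.2
        problem, z, _ = make_toy_problem(n, k, mu, omega, sigma, seed=33)
        rng = np.random.default_rng(2)
        om = np.array([[omega**2]])
        a, b = np.array([sigma]), np.array([0.0])
        cm, cc, _ = conditional_moments(problem, np.array([mu]), om, a, b, rng,
                                        n_iter=600, burn=150)
        draws, logq = draw_is_proposal(cm, cc, np.array([True]), 8000, rng)

        def ll(m):
            return is_loglik_fixed(problem, np.array([m]), om, a, b, draws, logq,
                                   np.array([True]))

        h = 1e-2
        score_fim = float(np.sum(((ll(mu + h) - ll(mu - h)) / (2 * h)) ** 2))
        hess_fim = float(-(ll(mu + h).sum() + ll(mu - h).sum() - 2 * ll(mu).sum()) / h**2)
        exact_scores = k * (z.mean(axis=1) - mu) / (sigma**2 + k * omega**2)
        assert score_fim == pytest.approx(float(np.sum(exact_scores**2)), rel=0.1)
        assert hess_fim == pytest.approx(n / (omega**2 + sigma**2 / k), rel=0.15)


class TestFimOnFit:
    @pytest.fixture(scope="class")
    def plain_fit(self, reference_model):
        # one-study dataset under the diagonal variability model, with a
        # visible direct-absorption path so every direction is informed
        spec1 = ip.candidate_models()[1]
        respec = ip.RandomEffectSpec(omega=(0.3, 0.2, 0.25, 0.25, 0.2, 0.2))
        d = ip.default_designs()[0]
        design = ip.StudyDesign(
            study_id=d.study_id, n_subjects=30, dose_amount=12.0, dose_per_kg=False,
            schedule=d.schedule, lloq=d.lloq, error=d.error,
            cov_mean=d.cov_mean, cov_sd=d.cov_sd,
        )
        theta1 = ip.FixedEffects(
            pop={"tau": 5.62, "VI": 0.135, "alpha": 0.05, "ka1": 0.01,
                 "ka2": 0.0128, "ke": 0.113}
        )
        sim = ip.simulate_study(design, theta1, spec1, respec, seed=55, censor=False)
        cfg = ip.FitConfig(
            seed=3, n_exploration=120, n_smoothing=120, mh_per_iteration=2,
            n_posterior=150, posterior_burn=50, refine_rounds=3, refine_maxiter=8,
        )
        return sim, ip.saem_fit(sim.dataset, spec1, cfg)

    def test_hessian_route_flags_flat_directions(self, plain_fit):
        # along the weakly identified volume/elimination trade-off the
        # numeric Hessian of the IS surface loses curvature; the failure
        # must be an informative error naming the directions, not silence
        sim, fit = plain_fit
        with pytest.raises(np.linalg.LinAlgError, match="_pop"):
            fim_and_rse(sim.dataset, fit, method="hessian", n_samples=400,
                        seed=11, step=1e-2)

    def test_rse_reported_on_natural_scale(self, plain_fit):
        sim, fit = plain_fit
        fim, cov, rse = fim_and_rse(sim.dataset, fit, n_samples=400, seed=4)
        assert (rse > 0).all()
        assert list(rse.index) == fit.parameter_labels()
        # delta method: for a log-transformed parameter the natural-scale
        # relative SE equals the SD of the log estimate
        lbl = "ke_pop"
        i = fit.parameter_labels().index(lbl)
        sd_log = np.sqrt(np.linalg.inv(fim)[i, i])
        assert rse[lbl] == pytest.approx(100 * sd_log, rel=1e-6)

    def test_unknown_method_rejected(self, plain_fit):
        sim, fit = plain_fit
        with pytest.raises(ValueError):
            fim_and_rse(sim.dataset, fit, method="bogus")
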