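"""Between-subject variability model: Omega assembly, covariate links,
log-normal sampling properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import insupop as ip
from insupop.model_core import PARAM_NAMES


def _cov(bw=74.0, bh=175.0, age=42.0):
    return ip.derive_covariates(BW=bw, BH=bh, AGE=age)


class TestDeriveCovariates:
    def test_bmi_and_bsa_formulas(self):
        cv = _cov()
        assert cv.BMI == pytest.approx(24.163, abs=0.01)
        assert cv.BSA == pytest.approx(1.893, abs=0.01)

    def test_bmi_unit_identity_at_one_metre(self):
        # at BH = 100 cm, BMI equals BW numerically
        assert ip.derive_covariates(BW=55.0, BH=100.0, AGE=30.0).BMI == pytest.approx(55.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ip.derive_covariates(BW=-1.0, BH=175.0, AGE=40.0)

    def test_inconsistent_bmi_rejected(self):
        with pytest.raises(ValueError):
            ip.CovariateVector(AGE=40, BW=74, BH=175, BMI=30.0, BSA=1.9)


class TestBuildOmega:
    def test_diagonal_when_no_correlations(self):
        spec = ip.RandomEffectSpec(omega=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6))
        om = ip.build_omega(spec)
        assert np.allclose(om, np.diag(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]) ** 2))

    def test_selected_model_zero_pattern(self, reference_model):
        # tau, alpha, ka1 independent; VI-ka2, VI-ke, ka2-ke coupled
        _, _, respec = reference_model
        om = ip.build_omega(respec)
        idx = {n: i for i, n in enumerate(PARAM_NAMES)}
        for p in ("tau", "alpha", "ka1"):
            row = om[idx[p]].copy()
            row[idx[p]] = 0.0
            assert np.all(row == 0.0)
        for p1, p2 in (("VI", "ka2"), ("VI", "ke"), ("ka2", "ke")):
            assert om[idx[p1], idx[p2]] != 0.0
        assert om[idx["VI"], idx["ka2"]] == pytest.approx(0.319 * 0.322 * 0.681, rel=1e-12)

    def test_non_psd_combination_rejected(self):
        spec = ip.RandomEffectSpec(
            omega=(1.0,) * 6,
            rho={("VI", "ka2"): 0.9, ("VI", "ke"): 0.9, ("ka2", "ke"): -0.9},
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            ip.build_omega(spec)

    def test_rho_bounds_enforced(self):
        with pytest.raises(ValueError):
            ip.RandomEffectSpec(omega=(1.0,) * 6, rho={("VI", "ka2"): 1.0})


class TestIndividualParams:
    def test_reference_subject_equals_population(self, reference_model):
        theta, spec, _ = reference_model
        cv = _cov()
        p = ip.individual_params(theta, spec, cv, cv, np.zeros(6))
        for name in PARAM_NAMES:
            assert getattr(p, name) == pytest.approx(theta.pop[name])

    def test_bmi_link_shifts_ka2(self, reference_model):
        theta, spec, _ = reference_model
        ref = _cov()
        # subject whose BMI sits exactly one unit above the reference
        cov = ip.derive_covariates(BW=(ref.BMI + 1.0) * 1.75**2, BH=175.0, AGE=42.0)
        p = ip.individual_params(theta, spec, cov, ref, np.zeros(6))
        assert p.ka2 == pytest.approx(0.0128 * np.exp(-0.0865), rel=1e-6)
        assert p.ka2 == pytest.approx(0.011739, abs=2e-6)

    def test_centering_invariance(self, reference_model):
        # adding a constant to BMI of subject and reference changes nothing
        theta, spec, _ = reference_model
        eta = np.array([0.1, -0.2, 0.3, 0.0, 0.2, -0.1])
        shift = 3.0

        def with_bmi(bmi):
            return ip.derive_covariates(BW=bmi * 1.70**2, BH=170.0, AGE=40.0)

        p1 = ip.individual_params(theta, spec, with_bmi(25.0), with_bmi(24.0), eta)
        p2 = ip.individual_params(theta, spec, with_bmi(25.0 + shift), with_bmi(24.0 + shift), eta)
        assert p1.ka2 == pytest.approx(p2.ka2, rel=1e-12)

    def test_no_beta_reduces_to_plain_lognormal(self, reference_model):
        theta, _, _ = reference_model
        plain = ip.ModelSpec(1)
        theta0 = ip.FixedEffects(pop=dict(theta.pop))
        eta = np.array([0.5, -0.5, 0.2, 0.1, -0.3, 0.4])
        p = ip.individual_params(theta0, plain, _cov(60, 160, 30), _cov(), eta)
        for i, name in enumerate(PARAM_NAMES):
            assert getattr(p, name) == pytest.approx(theta.pop[name] * np.exp(eta[i]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sampled_params_positive_with_ordered_kd(self, reference_model, seed):
        theta, spec, respec = reference_model
        eta = ip.sample_eta(respec, 5, seed)
        for e in eta:
            p = ip.individual_params(theta, spec, _cov(), _cov(), e)
            assert min(p.tau, p.VI, p.alpha, p.ka1, p.ka2, p.ke) > 0
            assert p.kd >= p.ka2

    def test_missing_beta_rejected(self, reference_model):
        _, spec, _ = reference_model
        theta_nobeta = ip.FixedEffects(
            pop={"tau": 5.6, "VI": 0.13, "alpha": 0.015, "ka1": 1e-4, "ka2": 0.013, "ke": 0.11}
        )
        with pytest.raises(ValueError, match="beta"):
            ip.individual_params(theta_nobeta, spec, _cov(), _cov(), np.zeros(6))


class TestSampleEta:
    def test_seed_reproducibility(self, reference_model):
        _, _, respec = reference_model
        assert np.array_equal(ip.sample_eta(respec, 50, 11), ip.sample_eta(respec, 50, 11))

    def test_zero_omega_gives_zero_draws(self):
        spec = ip.RandomEffectSpec(omega=(0.0,) * 6)
        assert np.all(ip.sample_eta(spec, 100, 0) == 0.0)

    def test_empirical_correlation_matches_declared(self, reference_model):
        _, _, respec = reference_model
        eta = ip.sample_eta(respec, 100_000, 2024)
        idx = {n: i for i, n in enumerate(PARAM_NAMES)}
        r = np.corrcoef(eta[:, idx["VI"]], eta[:, idx["ka2"]])[0, 1]
        assert r == pytest.approx(0.681, abs=0.01)

    def test_lognormal_median_property(self, reference_model):
        # the median individual parameter equals the population value
        theta, spec, respec = reference_model
        eta = ip.sample_eta(respec, 100_000, 5)
        cv = _cov()
        med_tau = np.median(theta.pop["tau"] * np.exp(eta[:, 0]))
        assert med_tau == pytest.approx(theta.pop["tau"], rel=0.01)


class TestCandidateModels:
    def test_fourteen_models_with_expected_structure(self):
        models = ip.candidate_models()
        assert sorted(models) == list(range(1, 15))
        assert models[1].n_rho == 0 and models[1].n_beta == 0
        assert models[2].corr_pairs == (("VI", "ka2"),)
        assert models[3].n_rho == 3
        for mid in range(4, 12):
            assert models[mid].n_beta == 1 and models[mid].n_rho == 3
        for mid in (12, 13, 14):
            assert models[mid].n_beta == 2 and models[mid].n_rho == 3
        link11 = models[11].links[0]
        assert (link11.covariate, link11.param, link11.log) == ("BMI", "ka2", False)
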