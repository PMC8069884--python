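"""Residual diagnostics, correlation scan and a visual predictive check.

Fits a reduced trial, then: tests each subject's weighted residuals for
normality (Shapiro-Wilk) and randomness (runs test), scans the empirical
Bayes random effects for correlations with covariates (this is how the
BMI -> ka2 link and the VI/ka2/ke correlation block were discovered), and
computes VPC prediction bands. Expect roughly 95% of subjects to pass each
residual test at the 5% level when the model is correct, and ~90% of the
observed percentile points to fall inside the 90% bands.
"""

import numpy as np

import insupop as ip

theta, spec, respec = ip.reference_model11()
designs = [
    ip.StudyDesign(
        study_id=d.study_id, n_subjects=12, dose_amount=d.dose_amount,
        dose_per_kg=d.dose_per_kg, schedule=d.schedule, lloq=d.lloq,
        error=d.error, cov_mean=d.cov_mean, cov_sd=d.cov_sd,
    )
    for d in ip.default_designs()
]
sim = ip.simulate_trial(designs, theta, spec, respec, seed=5, censor=False)
fit = ip.saem_fit(
    sim.dataset, spec,
    ip.FitConfig(seed=2, n_exploration=150, n_smoothing=150,
                 mh_per_iteration=2, refine_rounds=4, refine_maxiter=10),
)

report = ip.test_residuals(fit.iwres_by_subject())
print(f"Shapiro-Wilk pass rate: {report.pct_sw_pass:.1f}% of subjects")
print(f"runs-test pass rate:    {report.pct_runs_pass:.1f}% of subjects")

scan = ip.correlation_scan(fit.eta_mean, sim.dataset.covariate_frame().drop(columns="STUDY"))
print("\nstrongest correlations among random effects / covariates:")
print(scan.head(5).round(4).to_string(index=False))

res = ip.vpc(fit, sim.dataset, n_replicates=200, seed=9)
print(f"\nVPC: {res.coverage * 100:.0f}% of observed percentile points inside "
      f"their 90% bands ({res.n_outliers} outlier points)")
print(res.table.head(6).round(2).to_string(index=False))
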