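# Methods

## Model

### Structural kinetics

A subcutaneous lispro bolus enters a non-monomeric depot `Isc1` after a
subject-specific delay τ. From there insulin either dissociates into
monomers (`Isc2`, rate kd) or is absorbed directly (rate ka1); monomeric
insulin is absorbed with rate ka2 and plasma insulin is eliminated with
rate ke. The observed plasma concentration is y = Ip/VI. The system is
linear with eigenvalues −(ka1+kd), −ka2 and −ke, so `solve_pk` evaluates
the tri-exponential closed form; a numeric ODE oracle in the test suite
confirms agreement to 1e-8 relative. Unit bookkeeping: doses are converted
to μU per kg body weight (a fixed 12 U dose divided by the subject's
weight; weight-based dosing directly), VI to mL/kg, so y is in μU/mL with
no trailing factors, and the exposure identity ∫y dt = D/(ke·VI·BW) holds
exactly.

Because kd and ka2 are interchangeable the model is estimated with
α = kd − ka2, log-normal, which enforces kd ≥ ka2 and removes the label
ambiguity. If two eigenvalues coincide to within 1e-10 min⁻¹ the rates are
nudged apart by that tolerance instead of switching to a confluent
formula; under continuous parameter distributions exact coincidence has
probability zero, and the nudge changes predictions by less than the
arithmetic noise of the exponentials.

### Population model and error model

Individual log-parameters are linear in the fixed effects:
φ_j = A_j ξ + η_j with η_j ~ N(0, Ω), where ξ stacks the six log
population values and the covariate coefficients β, and A_j carries the
centered covariate values. Covariates are centered at the sample mean of
the analysis dataset (stored with the fit), since no external reference
value exists. BSA uses the Du Bois formula 0.007184·BW^0.425·BH^0.725 (the
standard choice; configurable by supplying covariates directly).

Ω is structured: diagonal variances for all six effects plus declared
correlation entries only (the 14 candidate models declare none, one, or
the full VI/ka2/ke block). Measurement error is SD = sqrt(a² + b²·y²) with
one (a, b) pair per study, all estimated jointly in one fit.

## Estimation

### SAEM

The E-step runs one persistent Metropolis–Hastings chain per subject
(vectorized across subjects): each transition is an independence proposal
from the marginal N(0, Ω) (prior and proposal cancel, so the ratio is the
observation term — rarely accepted for data-rich subjects but able to
jump between conditional modes, which the delay parameter induces), a
full-vector random-walk proposal along chol(Ω), and a componentwise
sweep, with per-subject proposal scales adapted toward 30% acceptance. The M-step is exact for the linear latent
model: generalized least squares for ξ on the smoothed sufficient
statistics, a structured projection of the smoothed residual second moment
for Ω, and a two-parameter numeric optimization per study for (a, b) —
the combined error model is not exponential-family, so the error update
maximizes the current simulated-residual likelihood and is then smoothed
with the SAEM step size (the saemix convention). Schedule: exploration
with step size 1 and simulated-annealing floors (variances and error may
shrink at most 5% per iteration), then smoothing with step (k − K)^−0.7
by default (the full-size recovery experiment uses a longer schedule with
exponent 0.6; see the acceptance script). Initial values: population values at typical literature
magnitudes (τ 10 min, VI 0.126 L/kg, α 0.01, ka1 0.001, ka2 0.01, ke
0.1 min⁻¹), all ω at 0.1, error (a, b) = (1, 0.1).

A log-normal prior on VI_pop (location 0.126 L/kg, log-SD 0.1) enters the
ξ update as a ridge term. The prior is what makes the distribution volume
a-posteriori identifiable: the likelihood carries a long, nearly flat
ridge along the VI/ke trade-off (total clearance ke·VI·BW is pinned by the
exposure identity, the split much less so).

### Penalized-likelihood polish

Stochastic approximation drifts very slowly along that ridge, so the SAEM
estimate is polished by direct ascent of the penalized marginal
likelihood. The marginal log-likelihood is estimated by importance
sampling with *fixed* multivariate-t (df 4) draws centered on each
subject's conditional distribution; with common random numbers the
estimate is a smooth deterministic function of the parameters and L-BFGS
can ascend it. Because fixed draws are only trustworthy near their
proposal, the ascent runs in short recentered rounds (refresh conditional
moments, one structured Ω EM step, L-BFGS over ξ, an error-parameter EM
pass), followed by iterating the Ω EM map to its fixed point — the
correlated block is its slowest component — and a short re-ascent of ξ
under the settled covariance. Defaults: up to 12 rounds of 128 fixed
draws per subject (the full-size experiment uses 288), early-stopped when the ξ step falls below 5e-3;
disable with `refine_rounds=0`.

The surface also has occasional secondary basins (delay multimodality and
the α/ka1 trade-off). `saem_fit_restarts` runs the whole pipeline with
several algorithm seeds and keeps the fit with the highest penalized
marginal log-likelihood under a common importance-sampling evaluation;
the full-size recovery experiment uses two restarts.

### Empirical Bayes estimates, likelihood, precision

EBEs are the per-subject conditional modes (Nelder–Mead from the
conditional mean; conditional means are available via
`ebe_method="mean"`). The reported marginal log-likelihood uses fresh
importance-sampling draws (default 5000 per subject) from the same
heavy-tailed conditional proposals, with its Monte-Carlo SE from the
normalized weight variance.

The Fisher information is computed on the estimation scale (logs for
positive parameters, raw β, Fisher-z for correlations) and mapped to the
natural scale through the diagonal Jacobian of the transforms;
RSE_i = 100·sqrt(C_ii)/|θ̂_i|. The default "score" method differentiates
per-subject importance-sampling log-likelihoods (common random numbers)
by central differences and sums the outer products of the per-subject
scores — the sample form of the information identity at the MLE. A
"hessian" method (numeric Hessian of the total IS log-likelihood) is
provided as an independent cross-check; along weakly identified
directions the log-sum-exp convexity of the IS estimate can overwhelm the
near-zero true curvature, in which case the method raises an error naming
the flat directions rather than returning a silently wrong matrix. The
test suite verifies both routes against the analytic information on a
conjugate linear-Gaussian toy.

RSEs for correlations are computed through the Fisher-z transform and are
therefore approximate near |ρ| → 1.

## Model comparison and diagnostics

Candidates are compared with BICc = −2lnL + ln(N)·P_R + ln(n_tot)·P_F
(P_R: ω, ρ, β; P_F: fixed effects and error coefficients — 18 parameters
for the diagonal model, 22 for the selected one). Selection discards
candidates with any RSE above 50% — the published decisions are
reproduced by the flag count alone, so the mean-RSE cap defaults to
infinity and is configurable — and takes the lowest BICc among survivors;
ties break toward fewer parameters, then lower model id.

Residual diagnostics run per subject: Shapiro–Wilk on the IWRES and a
Wald–Wolfowitz runs test on their signs (exact runs distribution up to
n = 20, normal approximation with continuity correction beyond; zero
residuals dropped; subjects with fewer than three residuals excluded and
logged). Testing per subject avoids the excessive power of one pooled
normality test on thousands of residuals.

The VPC simulates replicate datasets from the fitted model on the
subjects' own designs and covariates, bins by the nominal sampling times
(quantile bins for irregular designs; under-populated bins merge with a
neighbor), and reports the central 90% interval of each requested
percentile against the observed percentile. Replicates are not
LLOQ-censored by default while the observed data are, so at
low-concentration bins the observed percentiles sit near or above the
lower band — the same bias mechanism that produces low-bin outliers when
below-quantification records are discarded from real data.

## Synthetic data

`default_designs()` encodes the three study designs: cohort sizes
42/37/37, a fixed 12 U dose or 0.2 U/kg, the printed sampling schedules
(20, 32 and 29 samples to 480/720/480 min), assay LLOQs 5/5.5/5.6 μU/mL,
per-study error parameters, and cohort covariate summaries (e.g. study 1:
age 42±11 y, weight 74±10 kg, height 175±8 cm). Covariates are drawn from
independent truncated normals (floors: 18 y, 40 kg, 140 cm); no
covariate correlation is simulated because only marginal summaries are
available (a BW–BH correlation is configurable and defaults to zero —
this slightly widens the simulated BMI distribution relative to a real
cohort). Noise may drive a simulated record negative; records below the
study LLOQ are then *discarded*, not flagged, matching the analysis
protocol, so negatives never survive and time-zero samples (true
concentration zero) are almost entirely censored. The generator retains
the hidden truth (η and individual parameters per subject) for recovery
testing. Assay-failure exclusions are not simulated (no mechanism is
documented).

What passing tests on this generator do and do not show: they validate
the estimation and diagnostic machinery under the declared statistical
model (log-normal BSV, combined Gaussian error, independent truncated-
normal covariates); they do not probe within-subject variability,
covariate correlation structure, assay artifacts, or model
misspecification, none of which the generator emulates.

### Recovery experiments and censoring

The parameter-recovery experiment (the acceptance script and the
recovery test) simulates the full 116-subject trial at the reference
estimates and refits the same model, comparing estimates against the
generating values. For this experiment LLOQ discarding is bypassed:
value-based truncation is informative missingness, and an estimator that
ignores censoring — as the analysis protocol prescribes — is biased with
respect to the generating values on censored data (delay and distribution
volume shift by several reported SEs at the ~30% discard rate these
designs produce). The censoring mechanism itself is exercised where it is
the object of study: the percentile-lifting assertions and the VPC
outlier mechanism.

## Numerical choices and limitations

- Variance floors 1e-8 (random effects) and 1e-12 (error) keep the
  conditional densities proper in degenerate configurations; correlations
  are clipped to |ρ| ≤ 0.98 during estimation and the assembled Ω is
  shrunk toward its diagonal if an update leaves the PSD cone.
- All randomness flows from the single seed in `FitConfig` /
  function-level `seed` arguments; identical seeds give byte-identical
  datasets and chains.
- The SAEM exploration phase is a random walk along weakly identified
  directions; the polish stage removes most but not all of the resulting
  run-to-run variation. On simulated 116-subject trials the fixed effects
  are recovered within about one to three reported standard errors; the
  correlated-block entries are the least stable quantities.
- Problem sizes in the shipped tests and examples (12-subject cohorts,
  shortened SAEM schedules) are chosen so the default suite completes in
  minutes; the full-size experiment lives in the acceptance script and
  the recovery test.
- Single-bolus designs only; no within-subject variability, no
  multi-dose superposition, no infusion inputs, no censored-likelihood
  BQL handling (the protocol discards BQL records).
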