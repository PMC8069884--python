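"""Model assessment: per-subject residual tests, correlation discovery and
the visual predictive check.

Residuals are individual weighted residuals (IWRES). Normality is tested
per subject with Shapiro–Wilk and randomness with a Wald–Wolfowitz runs
test on the residual signs (exact runs distribution for small samples,
normal approximation with continuity correction above n = 20); testing per
subject avoids the excessive power of a single pooled normality test on
thousands of residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .population import build_omega

__all__ = [
    "runs_test",
    "test_residuals",
    "DiagnosticsReport",
    "correlation_scan",
    "vpc",
    "VPCResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Runs test
# ---------------------------------------------------------------------------

def _runs_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact pmf of the number of runs for n1 positives and n2 negatives;
    index r = number of runs (entries 0 and 1 unused)."""
    n = n1 + n2
    total = comb(n, n1, exact=True)
    pmf = np.zeros(n + 1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n1 - 1, k - 1, exact=True) * comb(n2 - 1, k - 1, exact=True)
        else:
            k = (r - 1) // 2
            ways = comb(n1 - 1, k, exact=True) * comb(n2 - 1, k - 1, exact=True) + comb(
                n1 - 1, k - 1, exact=True
            ) * comb(n2 - 1, k, exact=True)
        pmf[r] = ways / total
    return pmf


def runs_test(x, exact_max_n: int = 20) -> tuple[float, float]:
    """Wald–Wolfowitz runs test on the signs of ``x``; zeros are dropped.

    Returns (number of runs, two-sided p). Exact distribution for
    n ≤ ``exact_max_n``; otherwise the normal approximation with a
    continuity correction. Degenerate sequences (all one sign) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    n = s.size
    n1 = int((s > 0).sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        return 1.0, 1.0
    runs = int(1 + np.sum(s[1:] != s[:-1]))
    if n <= exact_max_n:
        pmf = _runs_pmf(n1, n2)
        cdf = float(pmf[: runs + 1].sum())
        sf = float(pmf[runs:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = 1.0 + 2.0 * n1 * n2 / n
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1))
        z = (runs - mu)
        z -= 0.5 * np.sign(z)  # continuity correction toward the mean
        z /= math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(runs), float(p)


@dataclass
class DiagnosticsReport:
    """Per-subject residual-test results and their aggregates."""

    per_subject: pd.DataFrame      # n, sw_p, runs_p, sw_pass, runs_pass
    excluded: tuple[str, ...]
    alpha: float

    @property
    def pct_sw_pass(self) -> float:
        return float(100.0 * self.per_subject["sw_pass"].mean())

    @property
    def pct_runs_pass(self) -> float:
        return float(100.0 * self.per_subject["runs_pass"].mean())

    def to_json(self, path) -> None:
        import json

        payload = {
            "alpha": self.alpha,
            "pct_sw_pass": self.pct_sw_pass,
            "pct_runs_pass": self.pct_runs_pass,
            "excluded": list(self.excluded),
            "per_subject": self.per_subject.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=bool)


def test_residuals(iwres_by_subject: dict, alpha: float = 0.05) -> DiagnosticsReport:
    """Shapiro–Wilk and runs tests applied to each subject's IWRES.

    Subjects with fewer than 3 residuals are excluded (and logged), not
    counted as failures. ``pass`` means p > alpha.
    """
    rows = {}
    excluded = []
    for sid, r in iwres_by_subject.items():
        r = np.asarray(r, dtype=float)
        if r.size < 3:
            excluded.append(str(sid))
            continue
        sw_p = float(stats.shapiro(r).pvalue)
        _, runs_p = runs_test(r)
        rows[sid] = {
            "n": r.size,
            "sw_p": sw_p,
            "runs_p": runs_p,
            "sw_pass": sw_p > alpha,
            "runs_pass": runs_p > alpha,
        }
    if excluded:
        logger.info("test_residuals: excluded %d subjects with <3 residuals", len(excluded))
    per_subject = pd.DataFrame.from_dict(rows, orient="index")
    return DiagnosticsReport(per_subject=per_subject, excluded=tuple(excluded), alpha=alpha)


# ---------------------------------------------------------------------------
# Correlation discovery
# ---------------------------------------------------------------------------

def correlation_scan(eta: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pearson r and two-sided p for every random-effect pair and every
    (random effect, covariate or log covariate) pair, ranked by p.

    This is the posterior analysis used to decide which correlations rho
    and covariate links beta deserve entry into a candidate model. Constant
    columns are skipped with a log message. Requires >= 10 subjects.
    """
    if len(eta) < 10:
        raise ValueError("correlation scan needs at least 10 subjects")
    rows = []

    def _ok(v: np.ndarray, name: str) -> bool:
        if np.std(v) == 0:
            logger.info("correlation_scan: skipping constant column %s", name)
            return False
        return True

    cols = list(eta.columns)
    for c1, c2 in combinations(cols, 2):
        v1, v2 = eta[c1].to_numpy(), eta[c2].to_numpy()
        if not (_ok(v1, c1) and _ok(v2, c2)):
            continue
        r, p = stats.pearsonr(v1, v2)
        rows.append({"kind": "eta-eta", "var1": c1, "var2": c2, "r": r, "p": p})
    if covariates is not None:
        cov_cols = {}
        for c in covariates.columns:
            v = covariates[c].to_numpy(dtype=float)
            cov_cols[c] = v
            if np.all(v > 0):
                cov_cols[f"ln({c})"] = np.log(v)
        for ec in cols:
            ev = eta[ec].to_numpy()
            if not _ok(ev, ec):
                continue
            for cc, cv in cov_cols.items():
                if not _ok(cv, cc):
                    continue
                r, p = stats.pearsonr(ev, cv)
                rows.append({"kind": "eta-cov", "var1": ec, "var2": cc, "r": r, "p": p})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Prediction bands per (time bin, percentile) plus observed percentiles."""

    table: pd.DataFrame        # bin_time, percentile, lower, upper, observed, n_obs, outlier
    n_replicates: int
    percentiles: tuple[float, ...]
    band_level: float

    @property
    def n_outliers(self) -> int:
        return int(self.table["outlier"].sum())

    @property
    def coverage(self) -> float:
        """Fraction of observed-percentile points inside their band."""
        return float(1.0 - self.table["outlier"].mean())

    def to_csv(self, path) -> None:
        """Bands as CSV: one row per (time bin, percentile)."""
        self.table.to_csv(path, index=False)


def vpc(
    fit,
    dataset,
    n_replicates: int = 200,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    band_level: float = 0.90,
    bins: np.ndarray | None = None,
    seed: int = 0,
    censor_replicates: bool = False,
    min_bin_obs: int = 3,
) -> VPCResult:
    """Visual predictive check of a fitted population model.

    Simulates ``n_replicates`` datasets from the fitted model (fresh random
    effects and noise per replicate, the subjects' own covariates, doses and
    observation times), computes each requested percentile per time bin per
    replicate, and returns the central ``band_level`` prediction interval of
    each percentile together with the observed percentile and an outlier
    flag. Default bins are the nominal sampling times (data are scheduled);
    pass quantile bin edges for irregular designs. Replicates are not
    LLOQ-censored by default, so discarded-BQL observed data sit high at
    low-concentration bins — the documented outlier mechanism.
    """
    from .likelihood import build_problem
    from .inference import _error_arrays

    if n_replicates < 100:
        raise ValueError("need n_replicates >= 100 for stable bands")
    problem = fit._problem if dataset is fit._dataset else build_problem(
        dataset, fit.spec, fit.cov_ref
    )
    rng = np.random.default_rng(seed)
    omega = build_omega(fit.random_effects)
    a, b = _error_arrays(fit, problem)
    xi = fit._xi()
    n = problem.n_subjects
    mean_phi = np.einsum("ndq,q->nd", problem.design, xi)

    t_flat = problem.times[problem.mask]
    z_flat = problem.obs[problem.mask]
    lloq_flat = np.concatenate(
        [
            np.full(int(problem.mask[j].sum()), s.lloq if s.lloq is not None else -np.inf)
            for j, s in enumerate(dataset.subjects)
        ]
    )

    if bins is None:
        uniq = np.unique(t_flat)
        if uniq.size <= 40:
            bin_idx = np.searchsorted(uniq, t_flat)
            bin_times = uniq
        else:
            edges = np.quantile(t_flat, np.linspace(0, 1, 13))
            bin_idx = np.clip(np.searchsorted(edges, t_flat, side="right") - 1, 0, 11)
            bin_times = np.array([t_flat[bin_idx == i].mean() for i in range(12)])
    else:
        edges = np.asarray(bins, dtype=float)
        bin_idx = np.clip(np.searchsorted(edges, t_flat, side="right") - 1, 0, len(edges) - 2)
        bin_times = 0.5 * (edges[:-1] + edges[1:])

    # merge under-populated bins with their left neighbor
    counts = np.bincount(bin_idx, minlength=len(bin_times))
    remap = np.arange(len(bin_times))
    for i in range(len(bin_times)):
        if 0 < counts[i] < min_bin_obs and i > 0:
            logger.info("vpc: merging bin at t=%.1f with neighbor", bin_times[i])
            remap[i] = remap[i - 1]
    bin_idx = remap[bin_idx]
    kept_bins = np.unique(bin_idx)

    chol = np.linalg.cholesky(omega + 1e-12 * np.eye(omega.shape[0]))
    rows = np.arange(n)
    sim_pct = np.empty((n_replicates, len(kept_bins), len(percentiles)))
    for rep in range(n_replicates):
        eta = rng.standard_normal((n, omega.shape[0])) @ chol.T
        y = problem.predict(mean_phi + eta, rows)
        sd = problem.error_sd(y, rows, a, b)
        z = y + sd * rng.standard_normal(y.shape)
        z_rep = z[problem.mask]
        keep = z_rep >= lloq_flat if censor_replicates else slice(None)
        zb = z_rep[keep]
        bb = bin_idx[keep]
        for bi, g in enumerate(kept_bins):
            vals = zb[bb == g]
            if vals.size == 0:
                sim_pct[rep, bi] = np.nan
            else:
                sim_pct[rep, bi] = np.percentile(vals, percentiles)

    lo_q, hi_q = (1 - band_level) / 2, 1 - (1 - band_level) / 2
    recs = []
    for bi, g in enumerate(kept_bins):
        obs_vals = z_flat[bin_idx == g]
        tmid = float(np.mean(t_flat[bin_idx == g]))
        for pi, pct in enumerate(percentiles):
            lower = float(np.nanquantile(sim_pct[:, bi, pi], lo_q))
            upper = float(np.nanquantile(sim_pct[:, bi, pi], hi_q))
            observed = float(np.percentile(obs_vals, pct))
            recs.append(
                {
                    "bin_time": tmid,
                    "percentile": pct,
                    "lower": lower,
                    "upper": upper,
                    "observed": observed,
                    "n_obs": int(obs_vals.size),
                    "outlier": not (lower <= observed <= upper),
                }
            )
    table = pd.DataFrame(recs)
    return VPCResult(
        table=table,
        n_replicates=n_replicates,
        percentiles=tuple(percentiles),
        band_level=band_level,
    )
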