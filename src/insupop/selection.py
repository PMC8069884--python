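"""Candidate-model ledger and the selection rule.

Fourteen variability models of increasing complexity are fitted; each row
of the ledger records the parameter count, the estimate precision (mean
RSE and the number of parameters with RSE > 50%), the fraction of subjects
passing the per-subject residual tests, and the corrected BIC. Selection
discards rows with imprecise estimates and takes the lowest BICc among the
survivors, with a documented tie-break (fewer parameters, then lower model
id).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .population import ModelSpec, candidate_models
from .inference import (
    bicc,
    count_parameters,
    fim_and_rse,
    loglik_importance_sampling,
)
from .saem import FitConfig, saem_fit
from .diagnostics import test_residuals

__all__ = ["LedgerRow", "run_candidate_ledger", "select_model", "ledger_frame"]

logger = logging.getLogger(__name__)


@dataclass
class LedgerRow:
    """One candidate model's summary in the comparison ledger."""

    model_id: int
    covariates: str
    correlations: str
    n_params: int
    mean_rse: float
    n_rse_gt_50: int
    pct_sw: float
    pct_runs: float
    bicc: float
    converged: bool = True
    message: str = ""
    fit: object | None = field(default=None, repr=False)


def _spec_labels(spec: ModelSpec) -> tuple[str, str]:
    cov = "; ".join(link.label for link in spec.links) or "-"
    corr = " ".join(f"rho_{p1},{p2}" for p1, p2 in spec.corr_pairs) or "-"
    return cov, corr


def run_candidate_ledger(
    dataset,
    model_ids=tuple(range(1, 15)),
    config: FitConfig | None = None,
    n_loglik_samples: int = 2000,
    n_fim_samples: int = 300,
    seed: int = 0,
    rse_threshold: float = 50.0,
    keep_fits: bool = False,
) -> list[LedgerRow]:
    """Fit each candidate and assemble its ledger row.

    A candidate that errors out is recorded with ``converged=False`` and
    the failure message, never dropped silently.
    """
    specs = candidate_models()
    rows: list[LedgerRow] = []
    for mid in model_ids:
        spec = specs[mid]
        cov_lbl, corr_lbl = _spec_labels(spec)
        pr, pf, total = count_parameters(spec, n_studies=len(dataset.studies))
        try:
            fit = saem_fit(dataset, spec, config)
            ll, _ = loglik_importance_sampling(dataset, fit, n_loglik_samples, seed=seed)
            _, _, rse = fim_and_rse(dataset, fit, n_samples=n_fim_samples, seed=seed)
            report = test_residuals(fit.iwres_by_subject())
            crit = bicc(ll, dataset.n_subjects, dataset.n_obs, pr, pf)
            rows.append(
                LedgerRow(
                    model_id=mid,
                    covariates=cov_lbl,
                    correlations=corr_lbl,
                    n_params=total,
                    mean_rse=float(rse.mean()),
                    n_rse_gt_50=int((rse > rse_threshold).sum()),
                    pct_sw=report.pct_sw_pass,
                    pct_runs=report.pct_runs_pass,
                    bicc=crit,
                    fit=fit if keep_fits else None,
                )
            )
            logger.info("model %d: BICc=%.2f mean RSE=%.2f%%", mid, crit, rse.mean())
        except Exception as exc:  # record, never drop silently
            logger.warning("model %d failed: %s", mid, exc)
            rows.append(
                LedgerRow(
                    model_id=mid,
                    covariates=cov_lbl,
                    correlations=corr_lbl,
                    n_params=total,
                    mean_rse=math.nan,
                    n_rse_gt_50=0,
                    pct_sw=math.nan,
                    pct_runs=math.nan,
                    bicc=math.nan,
                    converged=False,
                    message=str(exc),
                )
            )
    return rows


def ledger_frame(rows: list[LedgerRow]) -> pd.DataFrame:
    """The ledger as a table (CSV-ready, column layout of the usual report)."""
    return pd.DataFrame(
        [
            {
                "model": r.model_id,
                "covariates": r.covariates,
                "correlations": r.correlations,
                "n_params": r.n_params,
                "mean_rse": r.mean_rse,
                "n_rse_gt_50": r.n_rse_gt_50,
                "pct_sw_pass": r.pct_sw,
                "pct_runs_pass": r.pct_runs,
                "bicc": r.bicc,
                "converged": r.converged,
            }
            for r in rows
        ]
    )


def select_model(
    ledger: list[LedgerRow],
    rse_threshold: float = 50.0,
    mean_rse_cap: float = math.inf,
) -> tuple[int, pd.DataFrame]:
    """Select the most parsimonious precise candidate.

    Discards non-converged rows, rows with any RSE above ``rse_threshold``
    and rows with mean RSE above ``mean_rse_cap``; among survivors returns
    the argmin of BICc (ties: fewer parameters, then lower model id),
    together with an audit table giving each row's fate.
    """
    audit = []
    survivors = []
    for r in ledger:
        if not r.converged:
            fate = f"discarded: did not converge ({r.message})"
        elif r.n_rse_gt_50 > 0:
            fate = f"discarded: {r.n_rse_gt_50} parameter(s) with RSE > {rse_threshold:g}%"
        elif r.mean_rse > mean_rse_cap:
            fate = f"discarded: mean RSE {r.mean_rse:.2f}% > cap {mean_rse_cap:g}%"
        else:
            fate = "retained"
            survivors.append(r)
        audit.append({"model": r.model_id, "bicc": r.bicc, "fate": fate})
    if not survivors:
        raise ValueError(
            "all candidate models were discarded: "
            + "; ".join(a["fate"] for a in audit)
        )
    best = min(survivors, key=lambda r: (r.bicc, r.n_params, r.model_id))
    audit_df = pd.DataFrame(audit).sort_values("model", ignore_index=True)
    audit_df.loc[audit_df["model"] == best.model_id, "fate"] = "selected"
    return best.model_id, audit_df
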