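"""Dataset container and long-format CSV interchange.

The on-disk dialect is the de-facto population-PK long format (one row per
event): a dose row carries AMT (insulin units) at the injection time, and
observation rows carry DV (plasma concentration, μU/mL). Covariates are
repeated on every row of a subject. Records below the study's lower limit
of quantification are dropped at parse time, mirroring the protocol of the
clinical analyses this package emulates, and every filter is logged so the
record flow from raw file to analysis set is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import DoseEvent, PARAM_NAMES
from .population import CovariateVector, derive_covariates

__all__ = [
    "Subject",
    "Dataset",
    "parse_dataset",
    "write_dataset",
    "summarize_individuals",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("ID", "STUDY", "TIME", "DV", "AMT", "BW", "BH", "AGE")


@dataclass
class Subject:
    """One subject: observation vectors, dose event and covariates."""

    id: str
    study: str
    times: np.ndarray
    conc: np.ndarray
    dose: DoseEvent
    covariates: CovariateVector
    lloq: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError(f"subject {self.id}: times and conc differ in length")
        if len(np.unique(self.times)) != len(self.times):
            raise ValueError(f"subject {self.id}: duplicate observation times")

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """An analysis-ready set of subjects plus provenance of applied filters."""

    subjects: list[Subject]
    provenance: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    @property
    def studies(self) -> tuple[str, ...]:
        return tuple(sorted({s.study for s in self.subjects}))

    def covariate_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ID": s.id,
                "STUDY": s.study,
                "AGE": s.covariates.AGE,
                "BW": s.covariates.BW,
                "BH": s.covariates.BH,
                "BMI": s.covariates.BMI,
                "BSA": s.covariates.BSA,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows).set_index("ID")

    def mean_covariates(self) -> CovariateVector:
        """Database-mean covariate vector, the centering reference."""
        f = self.covariate_frame()
        return CovariateVector(
            AGE=f["AGE"].mean(),
            BW=f["BW"].mean(),
            BH=f["BH"].mean(),
            BMI=f["BMI"].mean(),
            BSA=f["BSA"].mean(),
        )


def parse_dataset(path, lloq_column: str = "LLOQ") -> Dataset:
    """Read and validate a long-format CSV into a :class:`Dataset`.

    Rows with DV below the subject's LLOQ (when an LLOQ column is present)
    are discarded with a logged count. Hard errors: missing required
    columns, a subject without exactly one dose row, duplicate observation
    times within a subject.
    """
    raw = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    n_bql = 0
    subjects: list[Subject] = []
    for sid, grp in raw.groupby("ID", sort=False):
        dose_rows = grp[grp["AMT"].notna() & (grp["AMT"] > 0)]
        if len(dose_rows) != 1:
            raise ValueError(
                f"subject {sid}: expected exactly one dose row, found {len(dose_rows)}"
            )
        dose_row = dose_rows.iloc[0]
        obs = grp[grp["DV"].notna()].copy()
        if lloq_column in grp.columns and obs[lloq_column].notna().any():
            keep = obs["DV"] >= obs[lloq_column]
            n_bql += int((~keep).sum())
            obs = obs[keep]
        first = grp.iloc[0]
        if {"BMI", "BSA"}.issubset(grp.columns) and not (
            pd.isna(first.get("BMI")) or pd.isna(first.get("BSA"))
        ):
            cov = CovariateVector(
                AGE=float(first["AGE"]),
                BW=float(first["BW"]),
                BH=float(first["BH"]),
                BMI=float(first["BMI"]),
                BSA=float(first["BSA"]),
            )
        else:
            cov = derive_covariates(float(first["BW"]), float(first["BH"]), float(first["AGE"]))
        lloq = None
        if lloq_column in grp.columns and not pd.isna(first.get(lloq_column)):
            lloq = float(first[lloq_column])
        subjects.append(
            Subject(
                id=str(sid),
                study=str(first["STUDY"]),
                times=obs["TIME"].to_numpy(dtype=float),
                conc=obs["DV"].to_numpy(dtype=float),
                dose=DoseEvent(amount=float(dose_row["AMT"]), time=float(dose_row["TIME"])),
                covariates=cov,
                lloq=lloq,
            )
        )
    if n_bql:
        logger.info("parse_dataset: discarded %d records below LLOQ", n_bql)
    return Dataset(
        subjects=subjects,
        provenance={"file": str(path), "n_bql_discarded": n_bql, "n_rows": len(raw)},
    )


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset in the long CSV dialect read by :func:`parse_dataset`.

    Weight-based doses are written as the absolute administered amount (U).
    """
    rows = []
    for s in dataset.subjects:
        base = {
            "ID": s.id,
            "STUDY": s.study,
            "BW": s.covariates.BW,
            "BH": s.covariates.BH,
            "AGE": s.covariates.AGE,
            "BMI": s.covariates.BMI,
            "BSA": s.covariates.BSA,
            "LLOQ": s.lloq if s.lloq is not None else np.nan,
        }
        amt = s.dose.amount * s.covariates.BW if s.dose.per_kg else s.dose.amount
        rows.append({**base, "TIME": s.dose.time, "DV": np.nan, "AMT": amt})
        for t, z in zip(s.times, s.conc):
            rows.append({**base, "TIME": t, "DV": z, "AMT": np.nan})
    cols = ["ID", "STUDY", "TIME", "DV", "AMT", "BW", "BH", "AGE", "BMI", "BSA", "LLOQ"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def summarize_individuals(fit_or_frame) -> pd.DataFrame:
    """Five-number summary (Min, Q1, Median, Q3, Max) of the individual
    parameter estimates, one row per kinetic parameter."""
    if isinstance(fit_or_frame, pd.DataFrame):
        frame = fit_or_frame
    else:
        frame = fit_or_frame.individual_params
    rows = {}
    for name in PARAM_NAMES:
        v = frame[name].to_numpy(dtype=float)
        rows[name] = {
            "Min": np.min(v),
            "Q1": np.quantile(v, 0.25),
            "Median": np.median(v),
            "Q3": np.quantile(v, 0.75),
            "Max": np.max(v),
        }
    out = pd.DataFrame(rows).T[["Min", "Q1", "Median", "Q3", "Max"]]
    out.index.name = "parameter"
    return out
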