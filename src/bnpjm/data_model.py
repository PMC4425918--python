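"""Cohort data structures, CSV I/O and preprocessing transforms.

The analysis operates on two linked tables:

* a *longitudinal* table in long format — one row per BNP assay, with the
  subject id, the visit time in years since study entry and the measured
  concentration in pg/ml;
* a *survival* table — one row per subject with the observed follow-up time,
  one event indicator per outcome (death; aortic-valve intervention) and the
  baseline covariates entering both submodels.

Preprocessing mirrors the analysis conventions: BNP is modelled on the
natural-log scale, and LV ejection fraction and creatinine are standardized
by dividing by a standard deviation.  The SDs used are recorded on the
:class:`Cohort` so that new subjects seen at prediction time are scaled by
the *training* constants, not their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCovariateError,
    DomainError,
    LinkageError,
    ParseError,
    SchemaError,
)

#: columns required in the longitudinal CSV
LONG_COLUMNS = ("subject_id", "time", "value")
#: columns required in the survival CSV
SURV_COLUMNS = (
    "subject_id",
    "obs_time",
    "status_death",
    "status_intervention",
    "ava",
    "age",
    "symptoms",
    "male",
    "lvef",
    "creatinine",
)
#: covariates standardized by their SD before modelling
DEFAULT_SCALED_COVARIATES = ("lvef", "creatinine")
#: binary columns (checked to be coded 0/1)
_BINARY_COLUMNS = ("status_death", "status_intervention", "symptoms", "male")


@dataclass
class Cohort:
    """A validated pair of linked longitudinal and survival tables.

    Attributes
    ----------
    longitudinal : pandas.DataFrame
        Columns ``subject_id``, ``time``, ``value`` and, after
        :func:`log_transform_biomarker`, ``value_log``.
    survival : pandas.DataFrame
        One row per subject, columns as in :data:`SURV_COLUMNS` and, after
        :func:`scale_by_sd`, ``<name>_scaled`` columns.
    scaling_constants : dict
        Covariate name -> the SD actually used for scaling.  Empty until
        :func:`scale_by_sd` runs.
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    scaling_constants: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    def subject_ids(self) -> np.ndarray:
        return self.survival["subject_id"].to_numpy()

    def measurements_for(self, subject_id) -> pd.DataFrame:
        return self.longitudinal[self.longitudinal["subject_id"] == subject_id]

    def copy(self) -> "Cohort":
        return Cohort(
            self.longitudinal.copy(),
            self.survival.copy(),
            dict(self.scaling_constants),
        )


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


def _coerce_numeric(df: pd.DataFrame, columns, table: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ParseError(
                f"{table} table column {col!r} is non-numeric or missing "
                f"at file row(s) {rows[:10]}"
            )
        df[col] = coerced
    return df


def validate_cohort(cohort: Cohort) -> Cohort:
    """Check every invariant of the cohort contract; return the cohort.

    Raises the most specific :class:`~bnpjm.errors.CohortError` subclass for
    the first violation found.
    """
    long_df, surv_df = cohort.longitudinal, cohort.survival

    if surv_df["subject_id"].duplicated().any():
        dup = surv_df.loc[surv_df["subject_id"].duplicated(), "subject_id"].tolist()
        raise LinkageError(f"duplicate subject_id in survival table: {dup[:10]}")
    if (surv_df["obs_time"] <= 0).any():
        bad = surv_df.loc[surv_df["obs_time"] <= 0, "subject_id"].tolist()
        raise DomainError(f"obs_time must be > 0; violated for subjects {bad[:10]}")
    for col in _BINARY_COLUMNS:
        if not surv_df[col].isin([0, 1]).all():
            raise DomainError(f"column {col!r} must be coded 0/1")

    if (long_df["time"] < 0).any():
        bad = long_df.index[long_df["time"] < 0].tolist()
        raise DomainError(f"negative visit times at longitudinal rows {bad[:10]}")
    if (long_df["value"] <= 0).any():
        bad = long_df.index[long_df["value"] <= 0].tolist()
        raise DomainError(
            f"biomarker values must be > 0 (log scale); rows {bad[:10]}"
        )

    long_ids = set(long_df["subject_id"])
    surv_ids = set(surv_df["subject_id"])
    orphans = sorted(long_ids - surv_ids, key=str)
    if orphans:
        raise LinkageError(
            f"subjects present in longitudinal but not survival table: {orphans[:10]}"
        )

    # no measurement after the subject's end of follow-up (closed interval)
    merged = long_df.merge(
        surv_df[["subject_id", "obs_time"]], on="subject_id", how="left"
    )
    late = merged["time"] > merged["obs_time"] + 1e-12
    if late.any():
        bad = merged.loc[late, "subject_id"].unique().tolist()
        raise LinkageError(
            f"measurement time exceeds obs_time for subjects {bad[:10]}"
        )
    return cohort


def make_cohort(long_df: pd.DataFrame, surv_df: pd.DataFrame) -> Cohort:
    """Assemble and validate a :class:`Cohort` from in-memory tables."""
    _require_columns(long_df, LONG_COLUMNS, "longitudinal")
    _require_columns(surv_df, SURV_COLUMNS, "survival")
    long_df = _coerce_numeric(long_df, ["time", "value"], "longitudinal")
    surv_df = _coerce_numeric(
        surv_df, [c for c in SURV_COLUMNS if c != "subject_id"], "survival"
    )
    long_df = (
        long_df.sort_values(["subject_id", "time"], kind="stable")
        .reset_index(drop=True)
    )
    surv_df = surv_df.sort_values("subject_id", kind="stable").reset_index(drop=True)
    return validate_cohort(Cohort(long_df, surv_df))


def load_cohort(long_path, surv_path) -> Cohort:
    """Read the two CSV files and return a validated :class:`Cohort`."""
    long_df = pd.read_csv(long_path)
    surv_df = pd.read_csv(surv_path)
    return make_cohort(long_df, surv_df)


def write_cohort(cohort: Cohort, long_path, surv_path) -> None:
    """Write the raw (unprocessed) columns of a cohort to two CSV files.

    Uses the shortest round-trippable float representation, so write->load
    reproduces every field exactly.
    """
    cohort.longitudinal[list(LONG_COLUMNS)].to_csv(long_path, index=False)
    cohort.survival[list(SURV_COLUMNS)].to_csv(surv_path, index=False)


def log_transform_biomarker(cohort: Cohort) -> Cohort:
    """Add ``value_log`` = ln(value); the raw value column is retained."""
    values = cohort.longitudinal["value"]
    if (values <= 0).any():
        bad = cohort.longitudinal.index[values <= 0].tolist()
        raise DomainError(
            f"cannot log-transform non-positive biomarker values at rows {bad[:10]}"
        )
    long_df = cohort.longitudinal.copy()
    long_df["value_log"] = np.log(values.to_numpy(dtype=float))
    return replace(cohort, longitudinal=long_df)


def scale_by_sd(
    cohort: Cohort,
    covariates=DEFAULT_SCALED_COVARIATES,
    constants: dict | None = None,
) -> Cohort:
    """Standardize covariates by dividing by an SD; record the SDs used.

    By default each SD is the sample SD (n-1 denominator) of the covariate in
    this cohort's survival table.  Passing ``constants`` overrides that — the
    mechanism by which subjects seen at prediction time are scaled by the
    training cohort's SDs.
    """
    surv = cohort.survival.copy()
    used = dict(cohort.scaling_constants)
    for name in covariates:
        if name not in surv.columns:
            raise SchemaError(f"unknown covariate {name!r} for SD scaling")
        if constants is not None and name in constants:
            sd = float(constants[name])
        else:
            sd = float(surv[name].std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateCovariateError(
                f"covariate {name!r} has zero or undefined SD ({sd}); cannot scale"
            )
        surv[f"{name}_scaled"] = surv[name] / sd
        used[name] = sd
    return Cohort(cohort.longitudinal.copy(), surv, used)


def preprocess(
    cohort: Cohort,
    covariates=DEFAULT_SCALED_COVARIATES,
    constants: dict | None = None,
) -> Cohort:
    """Log-transform the biomarker and SD-scale the named covariates."""
    return scale_by_sd(log_transform_biomarker(cohort), covariates, constants)
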