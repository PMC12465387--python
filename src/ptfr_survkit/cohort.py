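"""Right-censored survival cohorts: validation, CSV I/O, stratified splitting.

A cohort records, per subject, the observed follow-up time ``min(T_i, C_i)``
in days, the event indicator (1 = death observed, 0 = censored) and a numeric
covariate matrix.  The latent pair (event time ``T_i``, censoring time
``C_i``) is never jointly observed; every estimator downstream works from
``(time_observed, event)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalCohort",
    "HEART_FAILURE_COVARIATES",
    "read_cohort_csv",
    "write_cohort_csv",
    "train_test_split",
    "CohortValidationError",
    "SchemaError",
]

#: Canonical covariate order of the heart-failure clinical-records schema.
HEART_FAILURE_COVARIATES = [
    "age",
    "anaemia",
    "creatinine_phosphokinase",
    "diabetes",
    "ejection_fraction",
    "high_blood_pressure",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "sex",
    "smoking",
]


class CohortValidationError(ValueError):
    """Raised when a table violates a cohort invariant (non-positive times,
    non-binary events, missing values — rejected, never imputed)."""


class SchemaError(KeyError):
    """Raised when an expected column is absent from the input table."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Validated right-censored survival data for ``n`` subjects.

    Parameters
    ----------
    subject_id : array of opaque identifiers, length n
    time_observed : float array, days, strictly positive
    event : int array in {0, 1}; 1 = event observed, 0 = censored
    covariates : (n, p) float matrix, no missing values
    covariate_names : ordered labels for the p columns
    """

    subject_id: np.ndarray
    time_observed: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id))
        object.__setattr__(
            self, "time_observed", np.asarray(self.time_observed, dtype=float)
        )
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(self.time_observed), -1)
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        self._validate()

    def _validate(self) -> None:
        n = len(self.time_observed)
        if n < 1:
            raise CohortValidationError("cohort must not be empty")
        if len(self.subject_id) != n or len(self.event) != n:
            raise CohortValidationError("field lengths disagree")
        t = self.time_observed
        if not np.all(np.isfinite(t)):
            raise CohortValidationError("non-finite follow-up time")
        if np.any(t <= 0):
            bad = int(np.flatnonzero(t <= 0)[0])
            raise CohortValidationError(
                f"non-positive follow-up time at row {bad} (time={t[bad]!r})"
            )
        if not np.isin(self.event, (0, 1)).all():
            raise CohortValidationError("event indicator must be 0 or 1")
        if self.covariates.size and self.covariates.shape[0] != n:
            raise CohortValidationError("covariate matrix row count mismatch")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise CohortValidationError("covariate_names/columns mismatch")
        if self.covariates.size and not np.all(np.isfinite(self.covariates)):
            raise CohortValidationError(
                "missing or non-finite covariate values (imputation is not supported)"
            )

    # -- convenience ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.time_observed)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        """Covariates + ``time`` + ``event`` as a DataFrame (modelling view)."""
        df = pd.DataFrame(self.covariates, columns=list(self.covariate_names))
        df.insert(0, "subject_id", self.subject_id)
        df["time"] = self.time_observed
        df["event"] = self.event
        return df

    def subset(self, index: np.ndarray) -> "SurvivalCohort":
        index = np.asarray(index)
        return SurvivalCohort(
            subject_id=self.subject_id[index],
            time_observed=self.time_observed[index],
            event=self.event[index],
            covariates=self.covariates[index],
            covariate_names=self.covariate_names,
        )

    def replace_times(self, new_times: np.ndarray) -> "SurvivalCohort":
        return SurvivalCohort(
            subject_id=self.subject_id,
            time_observed=np.asarray(new_times, dtype=float),
            event=self.event,
            covariates=self.covariates,
            covariate_names=self.covariate_names,
        )


def _frame_to_cohort(
    df: pd.DataFrame, time_col: str, event_col: str, covariate_cols: list[str]
) -> SurvivalCohort:
    for col in [time_col, event_col, *covariate_cols]:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from input")
    numeric = df[[time_col, event_col, *covariate_cols]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna() & df[[time_col, event_col, *covariate_cols]].notna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise CohortValidationError(f"non-numeric cell in row {row}")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise CohortValidationError(f"missing value in row {row} (rejected, not imputed)")
    subject_id = (
        df["subject_id"].to_numpy() if "subject_id" in df.columns else np.arange(len(df))
    )
    return SurvivalCohort(
        subject_id=subject_id,
        time_observed=numeric[time_col].to_numpy(),
        event=numeric[event_col].to_numpy(),
        covariates=numeric[covariate_cols].to_numpy(),
        covariate_names=tuple(covariate_cols),
    )


def read_cohort_csv(path, schema="heart_failure") -> SurvivalCohort:
    """Read and validate a survival table from CSV.

    ``schema`` is either the string ``"heart_failure"`` (Kaggle heart-failure
    clinical-records column set: 11 covariates plus ``time`` in days and
    ``DEATH_EVENT``) or a mapping ``{"time": col, "event": col,
    "covariates": [cols]}`` for generic tables.
    """
    df = pd.read_csv(path)
    if schema == "heart_failure":
        return _frame_to_cohort(df, "time", "DEATH_EVENT", HEART_FAILURE_COVARIATES)
    if isinstance(schema, dict):
        return _frame_to_cohort(
            df, schema["time"], schema["event"], list(schema.get("covariates", []))
        )
    raise ValueError(f"unknown schema {schema!r}")


def write_cohort_csv(cohort: SurvivalCohort, path) -> None:
    """Serialize a cohort in the generic schema (round-trips through
    ``read_cohort_csv`` with the matching column map)."""
    cohort.to_frame().to_csv(path, index=False)


def train_test_split(
    cohort: SurvivalCohort, train_fraction: float, seed: int
) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Disjoint train/test partition, stratified on the event indicator.

    Stratification keeps events in both parts, which small cohorts need for
    the downstream fits; the partition is deterministic for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = [rng.permutation(np.flatnonzero(cohort.event == v)) for v in (1, 0)]
    # largest-remainder allocation so stratum train sizes add up to the
    # overall target even when both strata round the same way
    total_target = int(np.floor(train_fraction * cohort.n + 0.5))
    exact = [train_fraction * len(s) for s in strata]
    counts = [int(np.floor(x)) for x in exact]
    order = np.argsort([c - x for c, x in zip(counts, exact)], kind="stable")
    for idx in order:
        if sum(counts) >= total_target:
            break
        if counts[idx] < len(strata[idx]):
            counts[idx] += 1
    train_mask = np.zeros(cohort.n, dtype=bool)
    for stratum, n_train in zip(strata, counts):
        train_mask[stratum[:n_train]] = True
    train = cohort.subset(np.flatnonzero(train_mask))
    test = cohort.subset(np.flatnonzero(~train_mask))
    if cohort.n_events >= 2 and (train.n_events == 0 or test.n_events == 0):
        raise ValueError(
            "partition left one side without events; use a larger cohort or "
            "a different seed"
        )
    return train, test
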