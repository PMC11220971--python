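"""The longitudinal analysis cohort: repeated outcomes joined to baseline covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Baseline covariates entering the trajectory model with class-common effects.
DEFAULT_COVARIATES = ("baseline_age", "sex", "abeta", "tau_ec", "adj_hv")


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class LongitudinalCohort:
    """Long-format repeated cognitive measurements plus per-subject covariates.

    Parameters
    ----------
    visits
        One row per cognitive assessment with columns ``subject_id``,
        ``time`` (years from the subject's cognitive baseline, first visit
        at 0) and ``outcome`` (cognitive composite, e.g. PACC-5).
    baseline
        One row per subject, indexed by ``subject_id``, holding the
        time-constant covariates (``baseline_age`` in years, ``sex`` coded
        1 = female, ``abeta`` DVR/SUVR, ``tau_ec`` SUVR, ``adj_hv`` mm^3,
        plus any extra columns downstream stages may use).

    Invariants (checked on construction): every subject has >= 2 visits,
    within-subject times are strictly increasing starting at 0, outcomes
    and the listed covariates are complete.
    """

    visits: pd.DataFrame
    baseline: pd.DataFrame
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.visits = self.visits.reset_index(drop=True)
        if self.baseline.index.name != "subject_id":
            if "subject_id" in self.baseline.columns:
                self.baseline = self.baseline.set_index("subject_id")
            else:
                raise CohortError("baseline table needs a subject_id index or column")
        if self.validate:
            self._check()

    def _check(self) -> None:
        required = {"subject_id", "time", "outcome"}
        missing = required - set(self.visits.columns)
        if missing:
            raise CohortError(f"visit table missing columns: {sorted(missing)}")
        if self.visits["outcome"].isna().any():
            bad = self.visits.loc[self.visits["outcome"].isna(), "subject_id"].unique()
            raise CohortError(f"missing outcomes for subjects: {list(bad)[:5]}")
        missing_cov = [c for c in self.covariate_columns if c not in self.baseline.columns]
        if missing_cov:
            raise CohortError(f"baseline table missing covariates: {missing_cov}")
        if self.baseline[list(self.covariate_columns)].isna().any().any():
            raise CohortError("covariates must be complete (complete-case cohort)")
        visit_subjects = set(self.visits["subject_id"])
        if visit_subjects - set(self.baseline.index):
            raise CohortError("visit table contains subjects absent from baseline table")
        for sid, grp in self.visits.groupby("subject_id", sort=False):
            t = grp["time"].to_numpy(dtype=float)
            if len(t) < 2:
                raise CohortError(f"subject {sid!r} has fewer than 2 visits")
            if t[0] != 0.0:
                raise CohortError(f"subject {sid!r} first visit time is {t[0]}, expected 0")
            if np.any(np.diff(t) <= 0):
                raise CohortError(f"subject {sid!r} visit times not strictly increasing")

    @property
    def subject_ids(self) -> np.ndarray:
        """Subject identifiers in first-appearance order of the visit table."""
        return self.visits["subject_id"].drop_duplicates().to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_visits_total(self) -> int:
        return len(self.visits)

    def outcomes(self) -> np.ndarray:
        return self.visits["outcome"].to_numpy(dtype=float)

    def subject_table(self, subject_id) -> pd.DataFrame:
        return self.visits[self.visits["subject_id"] == subject_id]

    def subset(self, subject_ids) -> "LongitudinalCohort":
        """Restrict the cohort to the given subjects (order preserved)."""
        keep = set(subject_ids)
        visits = self.visits[self.visits["subject_id"].isin(keep)].copy()
        baseline = self.baseline.loc[self.baseline.index.isin(keep)].copy()
        return LongitudinalCohort(visits, baseline, self.covariate_columns, validate=False)

    def covariate_matrix(self, columns=None) -> np.ndarray:
        """Per-subject covariate matrix aligned with :attr:`subject_ids`."""
        cols = list(columns if columns is not None else self.covariate_columns)
        return self.baseline.loc[self.subject_ids, cols].to_numpy(dtype=float)
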