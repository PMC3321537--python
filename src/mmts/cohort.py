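"""Labeled tabular cohorts: the input container for every MMTS stage.

A cohort is a subjects × features numeric table plus a per-subject class
label drawn from an ordered class set. For the OSA application the twelve
clinical features and the four-level severity grading (respiratory
disturbance index bands: <5 normal, 5–15 mild, 15–30 moderate, >30 severe)
are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MMTSError

#: Canonical OSA feature order; Gram-Schmidt processing always follows it.
OSA_FEATURES: tuple[str, ...] = (
    "gender", "age", "BW", "BH", "BMI", "SBP",
    "DBP", "ESS", "SOS", "DI3", "DI4", "PLM",
)

#: Severity classes in increasing order; also the classifier's tie-break order.
SEVERITY_ORDER: tuple[str, ...] = ("normal", "mild", "moderate", "severe")

LABEL_COLUMN = "label"


@dataclass
class CohortTable:
    """Subjects × features values with per-subject class labels.

    Parameters
    ----------
    feature_names:
        Ordered feature identifiers (length d). Fitting, orthogonal-array
        column assignment and weighting all use this order.
    values:
        float array, subjects × d, no missing values.
    labels:
        per-subject class id, each a member of ``class_order``.
    class_order:
        the declared ordered class set (default OSA severity order).
    """

    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_order: tuple[str, ...] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise MMTSError("values must be a 2-D subjects × features array")
        if self.values.shape[1] != len(self.feature_names):
            raise MMTSError(
                f"{len(self.feature_names)} feature names but values has "
                f"{self.values.shape[1]} columns"
            )
        if self.values.shape[0] != len(self.labels):
            raise MMTSError("labels length does not match number of subjects")
        if not np.all(np.isfinite(self.values)):
            raise MMTSError("cohort contains missing or non-finite values")
        unknown = set(self.labels) - set(self.class_order)
        if unknown:
            raise MMTSError(f"labels {sorted(unknown)} not in declared class set {self.class_order}")

    # -- accessors -----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes_present(self) -> list[str]:
        present = set(self.labels)
        return [c for c in self.class_order if c in present]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes_present()}

    def members(self, class_id: str) -> np.ndarray:
        """Rows belonging to one class."""
        if class_id not in self.class_order:
            raise MMTSError(f"unknown class '{class_id}'")
        return self.values[self.labels == class_id]

    def select_features(self, names: list[str]) -> "CohortTable":
        """Restrict to a feature subset, preserving the original order."""
        missing = [f for f in names if f not in self.feature_names]
        if missing:
            raise MMTSError(f"features {missing} not in cohort")
        ordered = [f for f in self.feature_names if f in set(names)]
        idx = [self.feature_names.index(f) for f in ordered]
        return CohortTable(ordered, self.values[:, idx], self.labels, self.class_order)

    # -- I/O -----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       class_order: tuple[str, ...] = SEVERITY_ORDER) -> "CohortTable":
        if LABEL_COLUMN not in df.columns:
            raise MMTSError(f"cohort table must have a '{LABEL_COLUMN}' column")
        features = [c for c in df.columns if c != LABEL_COLUMN]
        return cls(features, df[features].to_numpy(dtype=float),
                   df[LABEL_COLUMN].to_numpy(), class_order)

    @classmethod
    def from_csv(cls, path, class_order: tuple[str, ...] = SEVERITY_ORDER) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path), class_order)
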