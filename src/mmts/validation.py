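"""Measurement-scale validation (Stage 2, repeated for the reduced model).

A scale is usable when, for every class, examples from the other classes
("abnormal") sit much farther from that class's Mahalanobis space than the
class's own members ("normal"). The method itself states only "much larger";
this module makes that operational with a ratio criterion —
abnormal mean distance / normal mean distance > ``ratio_threshold``
(default 2) — and reports a one-sided Wilcoxon rank-sum p-value as a
descriptive aid, not a binding test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .cohort import CohortTable
from .config import ModelConfig
from .errors import MMTSError
from .space import MahalanobisSpace, distance_matrix

#: What the method prescribes when validation fails.
REMEDY_MESSAGE = (
    "measurement scale failed separability validation: return to the beginning "
    "of the whole problem and re-examine the completeness of the considered "
    "features and the representativeness of the collected examples"
)


@dataclass
class ClassValidation:
    class_id: str
    normal_mean_md: float
    abnormal_mean_md: float
    separation_ratio: float
    rank_sum_p: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "normal_mean_md": self.normal_mean_md,
            "abnormal_mean_md": self.abnormal_mean_md,
            "separation_ratio": self.separation_ratio,
            "rank_sum_p": self.rank_sum_p,
            "passed": self.passed,
        }


@dataclass
class ValidationReport:
    per_class: list[ClassValidation]
    passed: bool
    ratio_threshold: float

    def to_dict(self) -> dict:
        return {
            "per_class": [r.to_dict() for r in self.per_class],
            "passed": self.passed,
            "ratio_threshold": self.ratio_threshold,
            "criterion": "separation_ratio > ratio_threshold (package convention; "
                         "the method itself gives no quantitative criterion)",
        }


def validate_scale(spaces: list[MahalanobisSpace], cohort: CohortTable,
                   config: ModelConfig | None = None) -> ValidationReport:
    """Check abnormal-vs-normal distance separation for every class.

    For class *i*: normal distances are its own members' distances to space
    *i*; abnormal distances are every other subject's distance to space *i*.
    Overall failure is a reported outcome, not an exception — remediation
    (revisit features, recollect examples) is a human decision.
    """
    config = config or ModelConfig()
    present = cohort.classes_present()
    fitted = {s.class_id for s in spaces}
    missing = [c for c in present if c not in fitted]
    if missing:
        raise MMTSError(f"no fitted space for classes {missing}")
    if len(present) < 2:
        raise MMTSError("validation needs at least 2 classes (no abnormal examples otherwise)")

    D = distance_matrix(spaces, cohort.values)
    col = {c: j for j, c in enumerate(D.class_order)}
    records = []
    for c in present:
        own = cohort.labels == c
        normal = D.values[own, col[c]]
        abnormal = D.values[~own, col[c]]
        nm, am = float(normal.mean()), float(abnormal.mean())
        ratio = am / nm if nm > 0 else np.inf
        p = float(mannwhitneyu(abnormal, normal, alternative="greater").pvalue)
        records.append(ClassValidation(c, nm, am, float(ratio), p,
                                       bool(ratio > config.ratio_threshold)))
    return ValidationReport(records, all(r.passed for r in records), config.ratio_threshold)
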