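"""Stage 4: reduced model, weighted Mahalanobis distance, classification, metric.

The per-class spaces are refit on the selected feature subset R (original
column order preserved), each selected feature gets weight
w_l = Gain_l / Σ_{l∈R} Gain_l, and an example is assigned to the class
minimizing the weighted Mahalanobis distance

    WMD^(i) = (1/δ) · Σ_{l∈R} w_l · u_l² / ζ_l²,

with δ = |R|. With uniform weights this is (1/δ)× the unweighted reduced
distance, so the argmin — hence the classification — coincides with the
plain minimum-distance rule.

Evaluation uses the unweighted mean of per-class accuracies (macro-averaged
accuracy), the "Average" arithmetic of the source study's comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .cohort import CohortTable
from .config import ModelConfig
from .errors import MMTSError
from .screening import GainTable
from .space import MahalanobisSpace, fit_class_spaces, gs_transform
from .validation import ValidationReport, validate_scale

logger = logging.getLogger(__name__)


@dataclass
class ReducedModel:
    selected_features: list[str]
    weights: np.ndarray
    gains: np.ndarray
    spaces: list[MahalanobisSpace]
    class_order: tuple[str, ...]
    validation: ValidationReport | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def delta(self) -> int:
        """δ, the reduced feature count."""
        return len(self.selected_features)

    def space_of(self, class_id: str) -> MahalanobisSpace:
        for s in self.spaces:
            if s.class_id == class_id:
                return s
        raise MMTSError(f"no space for class '{class_id}'")

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "weights": self.weights.tolist(),
            "gains": self.gains.tolist(),
            "class_order": list(self.class_order),
            "spaces": [s.to_dict() for s in self.spaces],
            "validation": self.validation.to_dict() if self.validation else None,
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ReducedModel":
        return cls(
            selected_features=list(doc["selected_features"]),
            weights=np.asarray(doc["weights"], dtype=float),
            gains=np.asarray(doc["gains"], dtype=float),
            spaces=[MahalanobisSpace.from_dict(s) for s in doc["spaces"]],
            class_order=tuple(doc["class_order"]),
            warnings=list(doc.get("warnings", [])),
        )


def build_reduced_model(train: CohortTable, gain_table: GainTable,
                        config: ModelConfig | None = None,
                        validate: bool = True,
                        on_deficient: str = "error") -> ReducedModel:
    """Refit per-class spaces on the selected subset and attach gain weights.

    Weights normalize the selected features' effect gains to sum 1. A
    singleton fallback selection with nonpositive gain still gets weight 1
    but is logged as degraded. ``on_deficient='drop'`` lets a small class
    fall back to subspace distances instead of erroring when the selected
    subset still exceeds its rank.
    """
    config = config or ModelConfig()
    selected = gain_table.selected_features()
    if not selected:
        raise MMTSError("gain table has no selected features")
    # preserve original cohort column order
    selected = [f for f in train.feature_names if f in set(selected)]
    gains = gain_table.gains_of(selected)
    warnings: list[str] = []
    if np.any(gains <= 0):
        if len(gains) == 1:
            warnings.append(
                f"single selected feature '{selected[0]}' has nonpositive gain "
                f"{gains[0]:.4g}; degraded model"
            )
            weights = np.array([1.0])
        else:
            raise MMTSError("selected features must all have positive gain")
    else:
        weights = gains / gains.sum()
    sub = train.select_features(selected)
    spaces = fit_class_spaces(sub, config, on_deficient=on_deficient)
    for s in spaces:
        if s.is_deficient:
            dropped = [f for f, k in zip(s.feature_names, s.kept) if not k]
            warnings.append(f"reduced model, class '{s.class_id}' (n={s.n}): "
                            f"rank deficient; dropped GS components {dropped}")
    report = validate_scale(spaces, sub, config) if validate else None
    return ReducedModel(selected, weights, np.asarray(gains, dtype=float),
                        spaces, train.class_order, report, warnings)


def _restrict(model: ReducedModel, x, feature_names: list[str] | None) -> np.ndarray:
    """Pull the selected features out of ``x`` (mapping/Series or named array)."""
    if isinstance(x, dict):
        missing = [f for f in model.selected_features if f not in x]
        if missing:
            raise MMTSError(f"example is missing selected features {missing}")
        return np.array([float(x[f]) for f in model.selected_features])
    if isinstance(x, pd.Series):
        return _restrict(model, x.to_dict(), None)
    x = np.asarray(x, dtype=float)
    if feature_names is None:
        if x.shape == (model.delta,):
            return x
        raise MMTSError("positional example must carry exactly the selected "
                        "features, or pass feature_names")
    missing = [f for f in model.selected_features if f not in feature_names]
    if missing:
        raise MMTSError(f"example is missing selected features {missing}")
    idx = [feature_names.index(f) for f in model.selected_features]
    return x[idx]


def weighted_md(model: ReducedModel, class_id: str, x,
                feature_names: list[str] | None = None) -> float:
    """Weighted Mahalanobis distance from one example to one class.

    For a full-rank class space this is exactly
    (1/δ)·Σ_{l∈R} w_l·u_l²/ζ_l². A class fitted in subspace mode sums over
    its retained components only, with the weights renormalized over them
    and the prefactor set to the retained count, keeping distances
    comparable across classes.
    """
    xr = _restrict(model, x, feature_names)
    space = model.space_of(class_id)
    u = gs_transform(space, xr)
    k = space.kept
    w = model.weights[k]
    wsum = w.sum()
    if wsum <= 0:
        raise MMTSError(f"class '{class_id}': no positive weight on retained components")
    w = w / wsum
    return float(np.sum(w * u[k] ** 2 / space.zeta[k] ** 2) / int(k.sum()))


def weighted_distance_matrix(model: ReducedModel, X: CohortTable | pd.DataFrame | np.ndarray,
                             feature_names: list[str] | None = None) -> pd.DataFrame:
    """Examples × classes weighted distances (columns in class order)."""
    if isinstance(X, CohortTable):
        feature_names, X = X.feature_names, X.values
    elif isinstance(X, pd.DataFrame):
        feature_names = [c for c in X.columns if c != "label"]
        X = X[feature_names].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rows = [[weighted_md(model, s.class_id, x, feature_names) for s in model.spaces]
            for x in X]
    classes = [s.class_id for s in model.spaces]
    return pd.DataFrame(rows, columns=classes)


def classify(model: ReducedModel, X, feature_names: list[str] | None = None) -> np.ndarray:
    """Assign each example to the class with minimum weighted distance.

    Exact ties go to the first class in the declared class order and are
    logged.
    """
    W = weighted_distance_matrix(model, X, feature_names)
    vals = W.to_numpy()
    best = np.argmin(vals, axis=1)  # argmin takes the first minimum: tie-break rule
    for r in range(vals.shape[0]):
        ties = np.flatnonzero(vals[r] == vals[r, best[r]])
        if len(ties) > 1:
            logger.warning("example %d: exact distance tie among classes %s; "
                           "assigned '%s'", r,
                           [W.columns[t] for t in ties], W.columns[best[r]])
    return np.array([W.columns[b] for b in best], dtype=object)


@dataclass
class EvaluationReport:
    class_order: list[str]
    per_class_accuracy: dict[str, float]
    macro_accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "per_class_accuracy": self.per_class_accuracy,
            "macro_accuracy": self.macro_accuracy,
            "confusion": self.confusion.tolist(),
        }


def macro_average(per_class_rates) -> float:
    """Unweighted mean of per-class accuracy rates (the comparison-table 'Average')."""
    rates = np.asarray(per_class_rates, dtype=float)
    if rates.size == 0:
        raise MMTSError("no rates to average")
    return float(rates.mean())


def evaluate(y_true, y_pred, class_order) -> EvaluationReport:
    """Per-class accuracies, their macro average, and the confusion matrix.

    Every class in ``class_order`` must appear in ``y_true`` — a class with
    no true examples has an undefined accuracy.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise MMTSError("y_true and y_pred lengths differ")
    class_order = list(class_order)
    if set(y_true) - set(class_order) or set(y_pred) - set(class_order):
        raise MMTSError("labels outside the declared class order")
    cm = _sk_confusion(y_true, y_pred, labels=class_order)
    totals = cm.sum(axis=1)
    empty = [c for c, t in zip(class_order, totals) if t == 0]
    if empty:
        raise MMTSError(f"classes {empty} have no true examples; per-class accuracy undefined")
    rates = np.diag(cm) / totals
    per_class = {c: float(r) for c, r in zip(class_order, rates)}
    return EvaluationReport(class_order, per_class, macro_average(rates), cm)
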