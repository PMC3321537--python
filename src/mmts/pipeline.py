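"""End-to-end orchestration of the four MMTS stages.

Stage 1 fits a full-model Mahalanobis space per severity class; Stage 2
validates the measurement scale (abnormal examples must sit far from each
class's space); Stage 3 screens features with the orthogonal-array /
signal-to-noise experiment; Stage 4 refits on the selected subset, weights
components by normalized effect gains, revalidates, classifies the test set
by minimum weighted distance and reports macro-averaged accuracy.

All results go to machine-readable files; logs (with stage timings) go to
stderr. Reports contain no timestamps, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable
from .config import ModelConfig
from .errors import StageError, ValidationAbort
from .reduced import ReducedModel, build_reduced_model, classify, evaluate, \
    weighted_distance_matrix
from .screening import screen_features
from .simulate import GeneratorConfig, generate_cohort, split_cohort
from .space import fit_class_spaces
from .validation import REMEDY_MESSAGE, validate_scale

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs for one pipeline run: either CSV paths or generator settings."""

    train_csv: str | None = None
    test_csv: str | None = None
    generator: GeneratorConfig | None = None
    train_sizes: dict[str, int] | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    strict_validation: bool = False
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "train_csv": self.train_csv,
            "test_csv": self.test_csv,
            "generator": self.generator.to_dict() if self.generator else None,
            "train_sizes": self.train_sizes,
            "model": self.model.to_dict(),
            "strict_validation": self.strict_validation,
            "seed": self.seed,
        }


@dataclass
class RunReport:
    report: dict
    model: ReducedModel
    predictions: pd.DataFrame | None


def _stage(name):
    """Log a stage's wall time and re-raise its fatal errors with the stage name."""
    class _ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.3fs", name, dt)
                return False
            if isinstance(exc, (ValidationAbort, StageError)):
                return False
            raise StageError(name, exc) from exc
    return _ctx()


def _load_data(config: RunConfig) -> tuple[CohortTable, CohortTable | None]:
    if config.train_csv:
        train = CohortTable.from_csv(config.train_csv)
        test = CohortTable.from_csv(config.test_csv) if config.test_csv else None
        return train, test
    gen = config.generator or GeneratorConfig(seed=config.seed)
    cohort = generate_cohort(gen)
    return split_cohort(cohort, config.train_sizes, seed=config.seed)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all four stages; write report/model/prediction files if requested."""
    warnings: list[str] = []
    train, test = _load_data(config)
    logger.info("training cohort: %d subjects, %d features, classes %s",
                train.n_subjects, train.n_features, train.class_counts())

    with _stage("1-full-model"):
        # Small severity classes cannot support all d features at full rank
        # (centered rank <= n_i - 1), so the full model is fit in subspace
        # mode: degenerate Gram-Schmidt components are dropped and reported.
        full_spaces = fit_class_spaces(train, config.model, on_deficient="drop")
        for s in full_spaces:
            if s.is_deficient:
                dropped = [f for f, k in zip(s.feature_names, s.kept) if not k]
                warnings.append(f"full model, class '{s.class_id}' (n={s.n}): "
                                f"rank deficient; dropped GS components {dropped}")

    with _stage("2-validation"):
        validation = validate_scale(full_spaces, train, config.model)
        if not validation.passed:
            warnings.append(REMEDY_MESSAGE)
            logger.warning(REMEDY_MESSAGE)
            if config.strict_validation:
                raise ValidationAbort(REMEDY_MESSAGE)

    with _stage("3-screening"):
        oa, runs, gains = screen_features(train, config.model)
        warnings.extend(gains.warnings)
        logger.info("selected %d/%d features: %s", len(gains.selected_features()),
                    train.n_features, gains.selected_features())

    with _stage("4-reduced-model"):
        model = build_reduced_model(train, gains, config.model, on_deficient="drop")
        warnings.extend(model.warnings)
        if model.validation is not None and not model.validation.passed:
            warnings.append("reduced model: " + REMEDY_MESSAGE)
            if config.strict_validation:
                raise ValidationAbort("reduced model: " + REMEDY_MESSAGE)
        evaluation: dict = {}
        pred_train = classify(model, train)
        evaluation["train"] = evaluate(train.labels, pred_train,
                                       train.classes_present()).to_dict()
        predictions = None
        if test is not None:
            pred_test = classify(model, test)
            evaluation["test"] = evaluate(test.labels, pred_test,
                                          test.classes_present()).to_dict()
            W = weighted_distance_matrix(model, test)
            predictions = pd.DataFrame({"id": np.arange(test.n_subjects),
                                        "true_label": test.labels,
                                        "predicted_label": pred_test})
            for c in W.columns:
                predictions[f"wmd_{c}"] = W[c].to_numpy()
            logger.info("test macro accuracy: %.4f", evaluation["test"]["macro_accuracy"])

    report = {
        "software_version": __version__,
        "config": config.to_dict(),
        "validation": validation.to_dict(),
        "oa_shape": [oa.n_runs, oa.n_factors],
        "sn_runs": [r.to_dict() for r in runs],
        "gains": gains.to_dict(),
        "selected_features": model.selected_features,
        "weights": model.weights.tolist(),
        "validation_reduced": model.validation.to_dict() if model.validation else None,
        "evaluation": evaluation,
        "warnings": warnings,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2) + "\n")
        gains.to_frame().to_csv(out / "gains.csv", index=False)
        if predictions is not None:
            predictions.to_csv(out / "predictions.csv", index=False)
        if config.train_csv is None:
            train.to_csv(out / "train.csv")
            if test is not None:
                test.to_csv(out / "test.csv")
        logger.info("wrote results to %s", out)

    return RunReport(report, model, predictions)
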