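#!/usr/bin/env python
"""Sensitivity of every stage to the simulated severity signal strength.

Sweeps the between-adjacent-class mean shift (in pooled within-class SD
units) from a pure-noise cohort to an extreme 6-SD separation, running the
whole screen-refit-classify chain at each level over multiple seeds.
Writes results/effect_size_sensitivity.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mmts import (GeneratorConfig, build_reduced_model, classify, evaluate,
                  fit_class_spaces, generate_cohort, screen_features,
                  split_cohort, validate_scale)
from mmts.simulate import DEFAULT_INFORMATIVE

EFFECTS = (0.0, 0.75, 1.5, 3.0, 6.0)


def one_run(seed: int, effect: float) -> dict:
    cohort = generate_cohort(GeneratorConfig(seed=seed, effect_size=effect))
    train, test = split_cohort(cohort, seed=seed)
    spaces = fit_class_spaces(train, on_deficient="drop")
    report = validate_scale(spaces, train)
    _, _, table = screen_features(train)
    model = build_reduced_model(train, table, on_deficient="drop")
    pred = classify(model, test)
    ev = evaluate(test.labels, pred, test.classes_present())
    informative_pos = int((table.gains_of(list(DEFAULT_INFORMATIVE)) > 0).sum())
    return {
        "effect_size": effect,
        "seed": seed,
        "mean_separation_ratio": float(np.mean(
            [r.separation_ratio for r in report.per_class])),
        "n_selected": len(model.selected_features),
        "informative_with_positive_gain": informative_pos,
        "test_macro_accuracy": ev.macro_accuracy,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = [one_run(seed, e) for e in EFFECTS for seed in range(args.seeds)]
    df = pd.DataFrame(rows)
    args.results_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results_dir / "effect_size_sensitivity.csv", index=False)

    summary = df.groupby("effect_size").agg(
        sep_ratio=("mean_separation_ratio", "mean"),
        n_sel=("n_selected", "mean"),
        inf_pos=("informative_with_positive_gain", "mean"),
        macro_acc=("test_macro_accuracy", "mean"),
    )
    print(summary.round(3).to_string())
    print("\nReading: separation ratios grow with the signal but sit above 1 "
          "even at effect 0 (out-of-sample inflation at these class sizes); "
          "informative-feature recovery saturates by effect ~1.5; held-out "
          "macro accuracy approaches 1 as classes separate.")


if __name__ == "__main__":
    main()
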