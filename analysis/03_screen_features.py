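#!/usr/bin/env python
"""Stage 3: orthogonal-array / signal-to-noise feature screening.

Assigns the 12 clinical features to the columns of an L16 two-level
orthogonal array, scores every run's class separability with the
larger-the-better signal-to-noise ratio, and keeps features with positive
effect gain. Writes results/gains.csv and results/sn_runs.json.
"""

import argparse
import json
from pathlib import Path

from mmts import CohortTable, ModelConfig, screen_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--sn-exponent", type=int, choices=(1, 2), default=1)
    args = ap.parse_args()

    train = CohortTable.from_csv(args.results_dir / "cohort" / "train.csv")
    config = ModelConfig(sn_exponent=args.sn_exponent)
    oa, runs, table = screen_features(train, config)

    table.to_frame().to_csv(args.results_dir / "gains.csv", index=False)
    (args.results_dir / "sn_runs.json").write_text(json.dumps(
        [r.to_dict() for r in runs], indent=2) + "\n")

    print(f"orthogonal array: L{oa.n_runs} with {oa.n_factors} factor columns")
    scored = [r for r in runs if not r.skipped]
    print(f"scored runs: {len(scored)} "
          f"({sum(r.degenerate for r in scored)} rank deficient)")
    print(table.to_frame().round(3).to_string(index=False))
    print(f"selected ({len(table.selected_features())}): "
          f"{', '.join(table.selected_features())}")
    for w in table.warnings:
        print(f"warning: {w}")


if __name__ == "__main__":
    main()
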