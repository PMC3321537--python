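"""Stage 3: orthogonal-array feature screening with signal-to-noise scoring.

Each feature gets two levels — level 1 includes it when fitting the
per-class spaces, level 2 excludes it — and the features are assigned, in
cohort column order, to the columns of a two-level orthogonal array. Each
run (row) fits the spaces on its included subset and is scored with a
larger-the-better signal-to-noise ratio aggregated over ordered class pairs
(i, p), p ≠ i:

    η_ip = −10·log10( (1/n_i) · Σ_j (MD_j^(i→p) / MD_j^(i→i))^(−m) ),
    η    = Σ_{i} Σ_{p≠i} η_ip,

where MD_j^(i→p) is member j of class i's distance to class p's space and
m is ``sn_exponent`` (1 as the method defines it; 2 for the textbook form).
Large η means members sit close to their own space and far from the others.

A feature's effect gain is SN̄⁺ − SN̄⁻ — the mean η of runs that include it
minus the mean η of runs that exclude it; positive-gain features are kept.
Balance of the array makes these one-factor-at-a-time averages valid main
effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .cohort import CohortTable
from .config import ModelConfig
from .errors import MMTSError
from .space import distance_matrix, fit_class_spaces


@dataclass
class OrthogonalArray:
    """Runs × factors design matrix with entries in {1, 2}.

    Level 1 = feature included in the run, level 2 = excluded. Columns are
    balanced and pairwise orthogonal (every pair of columns shows each of
    the four level combinations equally often).
    """

    levels: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def included(self, run: int) -> np.ndarray:
        """Boolean mask of factors at level 1 in the given run."""
        return self.levels[run] == 1

    def check(self) -> None:
        """Brute-force balance and pairwise-orthogonality verification."""
        L = self.levels
        if not np.isin(L, (1, 2)).all():
            raise MMTSError("orthogonal array entries must be 1 or 2")
        for j in range(self.n_factors):
            if np.sum(L[:, j] == 1) * 2 != self.n_runs:
                raise MMTSError(f"column {j} is not balanced")
        for a, b in itertools.combinations(range(self.n_factors), 2):
            for la, lb in itertools.product((1, 2), repeat=2):
                cnt = np.sum((L[:, a] == la) & (L[:, b] == lb))
                if cnt * 4 != self.n_runs:
                    raise MMTSError(f"columns {a},{b} not pairwise orthogonal")


def build_orthogonal_array(n_factors: int) -> OrthogonalArray:
    """Smallest Sylvester-Hadamard two-level array L_N(2^(N−1)) covering ``n_factors``.

    N is the smallest power of two strictly greater than ``n_factors``
    (so the array has N−1 ≥ n_factors usable columns); the factors occupy
    the first ``n_factors`` columns. 3 factors → L4, 12 factors → L16.
    """
    if not (1 <= n_factors <= 255):
        raise MMTSError("n_factors must be between 1 and 255")
    N = 2
    while N - 1 < n_factors:
        N *= 2
    H = hadamard(N)
    levels = np.where(H[:, 1:n_factors + 1] > 0, 1, 2)
    return OrthogonalArray(levels.astype(int))


@dataclass
class SNRun:
    run_index: int
    included_features: list[str]
    eta: float
    eta_pairs: dict[tuple[str, str], float]
    degenerate: bool
    skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "run_index": self.run_index,
            "included_features": self.included_features,
            "eta": self.eta,
            "eta_pairs": {f"{i}->{p}": v for (i, p), v in self.eta_pairs.items()},
            "degenerate": self.degenerate,
            "skipped": self.skipped,
        }


@dataclass
class GainTable:
    """Per-feature SN̄⁺ / SN̄⁻ averages, effect gains and the keep decision."""

    features: list[str]
    sn_plus: np.ndarray
    sn_minus: np.ndarray
    gain: np.ndarray
    selected: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def selected_features(self) -> list[str]:
        return [f for f, s in zip(self.features, self.selected) if s]

    def gains_of(self, names: list[str]) -> np.ndarray:
        idx = [self.features.index(f) for f in names]
        return self.gain[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.features,
            "sn_plus": self.sn_plus,
            "sn_minus": self.sn_minus,
            "gain": self.gain,
            "selected": self.selected.astype(bool),
        })

    def to_dict(self) -> dict:
        return {"table": self.to_frame().to_dict(orient="records"),
                "warnings": self.warnings}


def run_sn_ratio(train: CohortTable, included_features: list[str],
                 config: ModelConfig | None = None):
    """Score one orthogonal-array run: fit spaces on a feature subset, return η.

    Returns ``(eta, eta_pairs, degenerate_flags)`` where ``degenerate_flags``
    maps class id → True when that class's space needed component dropping
    (subset too large for the class size). Own-class distances below
    ``md_floor`` are clipped before entering the denominator.
    """
    config = config or ModelConfig()
    if not included_features:
        raise MMTSError("cannot score a run with an empty feature set")
    sub = train.select_features(included_features)
    spaces = fit_class_spaces(sub, config, on_deficient="drop")
    degenerate = {s.class_id: s.is_deficient for s in spaces}
    classes = sub.classes_present()
    col = {c: j for j, c in enumerate(classes)}
    eta_pairs: dict[tuple[str, str], float] = {}
    for i in classes:
        D = distance_matrix(spaces, sub.members(i)).values
        own = np.maximum(D[:, col[i]], config.md_floor)
        for p in classes:
            if p == i:
                continue
            ratios = D[:, col[p]] / own
            mean_inv = float(np.mean(ratios ** (-float(config.sn_exponent))))
            eta_pairs[(i, p)] = -10.0 * np.log10(max(mean_inv, 1e-300))
    eta = float(sum(eta_pairs.values()))
    return eta, eta_pairs, degenerate


def screen_features(train: CohortTable, config: ModelConfig | None = None):
    """Run the full screening experiment.

    Builds the array for d features, scores every run whose included set is
    nonempty (empty runs are skipped and excluded from both averages),
    and computes each feature's effect gain. Features with positive gain are
    selected; if none is positive the single best feature is kept with a
    warning so a reduced model always exists.

    Returns ``(OrthogonalArray, list[SNRun], GainTable)``.
    """
    config = config or ModelConfig()
    if train.n_features < 2:
        raise MMTSError("screening needs at least 2 features")
    for c, cnt in train.class_counts().items():
        if cnt < 2:
            raise MMTSError(f"class '{c}' has fewer than 2 training members")
    oa = build_orthogonal_array(train.n_features)
    runs: list[SNRun] = []
    for r in range(oa.n_runs):
        mask = oa.included(r)
        feats = [f for f, m in zip(train.feature_names, mask) if m]
        if not feats:
            runs.append(SNRun(r, [], float("nan"), {}, False, skipped=True))
            continue
        eta, pairs, degen = run_sn_ratio(train, feats, config)
        runs.append(SNRun(r, feats, eta, pairs, any(degen.values())))
    scored = [r for r in runs if not r.skipped]
    if not scored:
        raise MMTSError("no scorable runs")
    if all(r.degenerate for r in scored):
        raise MMTSError(
            "every orthogonal-array run was rank deficient; collect more "
            "examples per class or screen fewer features"
        )

    warnings: list[str] = []
    d = train.n_features
    sn_plus = np.empty(d)
    sn_minus = np.empty(d)
    for j in range(d):
        inc = [r.eta for r in scored if oa.levels[r.run_index, j] == 1]
        exc = [r.eta for r in scored if oa.levels[r.run_index, j] == 2]
        sn_plus[j] = float(np.mean(inc))
        sn_minus[j] = float(np.mean(exc))
    gain = sn_plus - sn_minus
    selected = gain > 0
    if not selected.any():
        best = int(np.argmax(gain))
        selected[best] = True
        warnings.append(
            f"no feature had positive effect gain; keeping the best single "
            f"feature '{train.feature_names[best]}' (gain {gain[best]:.4g}) — "
            f"degraded model"
        )
    if any(r.degenerate for r in scored):
        ndeg = sum(r.degenerate for r in scored)
        warnings.append(f"{ndeg} of {len(scored)} runs were rank deficient and "
                        f"used subspace distances")
    table = GainTable(list(train.feature_names), sn_plus, sn_minus, gain,
                      selected, warnings)
    return oa, runs, table
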