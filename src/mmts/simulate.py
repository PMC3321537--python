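"""Synthetic OSA-like cohort generator.

The study cohort this package targets (86 subjects referred for suspected
obstructive sleep apnea, graded normal/mild/moderate/severe from the
respiratory disturbance index) is not publicly deposited, so every pipeline
stage is exercised on seeded synthetic cohorts instead. The generator
reproduces the experiment's *shape*:

* the 12-feature clinical schema (gender, age, weight, height, BMI, blood
  pressures, two sleep questionnaires, two desaturation indices, leg
  movements) with published cohort-level means/SDs/ranges as anchors;
* the published class sizes (24/29/19/14) and the 57/29 train/test split;
* a severity signal carried, by default, by the six features the original
  analysis found informative (age, BW, SBP, DBP, DI3, DI4) as
  severity-monotone mean shifts, while the remaining six stay uninformative.

Marginal SDs stay anchored at every effect size: the within-class SD is
shrunk so that within-class variance plus the between-class variance added
by the shifts reproduces the published marginal variance.

Structural realism that matters to the pipeline is kept exactly — the BMI
identity BMI = BW/(BH/100)², gender coded 1/2 with mean 1.23, PLM with a
point mass at 0 (published median 0), DI3/DI4 strongly correlated and
nonnegative. Distributional realism beyond that (the heavy right skew of
the desaturation indices) is only approximated: DI3/DI4 are truncated
normals on [0, 550] coupled by a Gaussian copula, so their mean/median skew
is not reproduced. See docs/methods.md for what this does and does not let
the tests conclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable, OSA_FEATURES, SEVERITY_ORDER
from .errors import MMTSError


@dataclass(frozen=True)
class FeatureParams:
    mean: float
    sd: float
    lo: float
    hi: float


#: Cohort-level anchors (mean, SD, range) for each clinical feature.
TABLE_ANCHORS: dict[str, FeatureParams] = {
    "gender": FeatureParams(1.23, 0.42, 1, 2),
    "age": FeatureParams(48.3, 11.87, 11, 78),
    "BW": FeatureParams(69.04, 11.31, 49, 116),
    "BH": FeatureParams(165.98, 7.34, 151, 184),
    "BMI": FeatureParams(24.98, 2.13, 18.34, 34.26),  # derived: BW/(BH/100)^2
    "SBP": FeatureParams(124.64, 17.62, 83, 178),
    "DBP": FeatureParams(81.23, 10.46, 53, 108),
    "ESS": FeatureParams(10.07, 6.38, 0, 24),
    "SOS": FeatureParams(50.23, 21.20, 18, 95),
    "DI3": FeatureParams(92.76, 121.66, 0, 550),
    "DI4": FeatureParams(92.47, 121.70, 0, 550),
    "PLM": FeatureParams(2.72, 8.68, 0, 47.1),
}

DEFAULT_CLASS_SIZES = {"normal": 24, "mild": 29, "moderate": 19, "severe": 14}
DEFAULT_TRAIN_SIZES = {"normal": 16, "mild": 23, "moderate": 10, "severe": 8}
DEFAULT_INFORMATIVE = ("age", "BW", "SBP", "DBP", "DI3", "DI4")

# features whose generation is structural, not a shiftable Gaussian
_SPECIAL = {"gender", "BMI", "PLM"}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``effect_size`` is the between-adjacent-class mean shift on informative
    features, in pooled within-class SD units; 0 produces a null cohort with
    no class signal.
    """

    seed: int = 0
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    effect_size: float = 1.5
    informative_features: tuple[str, ...] = DEFAULT_INFORMATIVE
    feature_params: dict[str, FeatureParams] = field(default_factory=lambda: dict(TABLE_ANCHORS))
    di_correlation: float = 0.95
    weight_height_correlation: float = 0.4
    female_fraction: float = 0.23
    plm_zero_fraction: float = 0.55
    class_order: tuple[str, ...] = SEVERITY_ORDER

    def validate(self) -> None:
        if self.effect_size < 0:
            raise MMTSError("effect_size must be >= 0")
        for c, n in self.class_sizes.items():
            if c not in self.class_order:
                raise MMTSError(f"class '{c}' not in class order {self.class_order}")
            if n < 2:
                raise MMTSError(f"class '{c}' must have at least 2 members")
        bad = set(self.informative_features) & _SPECIAL
        if bad:
            raise MMTSError(f"features {sorted(bad)} cannot carry a mean shift "
                            f"(categorical, derived, or zero-inflated)")
        for f in self.informative_features:
            if f not in self.feature_params:
                raise MMTSError(f"unknown informative feature '{f}'")
        for f, p in self.feature_params.items():
            if not (p.lo <= p.mean <= p.hi):
                raise MMTSError(f"feature '{f}': range [{p.lo}, {p.hi}] must contain mean {p.mean}")
        if not (-1 < self.di_correlation < 1) or not (-1 < self.weight_height_correlation < 1):
            raise MMTSError("correlations must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "class_sizes": dict(self.class_sizes),
            "effect_size": self.effect_size,
            "informative_features": list(self.informative_features),
            "feature_params": {f: [p.mean, p.sd, p.lo, p.hi]
                               for f, p in self.feature_params.items()},
            "di_correlation": self.di_correlation,
            "weight_height_correlation": self.weight_height_correlation,
            "female_fraction": self.female_fraction,
            "plm_zero_fraction": self.plm_zero_fraction,
            "class_order": list(self.class_order),
        }


def _class_offsets(config: GeneratorConfig) -> dict[str, float]:
    """Centered severity offsets o_c = c − c̄ weighted by class sizes.

    Centering keeps the marginal mean of informative features at its anchor
    regardless of effect size.
    """
    classes = [c for c in config.class_order if c in config.class_sizes]
    idx = {c: config.class_order.index(c) for c in classes}
    n = np.array([config.class_sizes[c] for c in classes], dtype=float)
    ix = np.array([idx[c] for c in classes], dtype=float)
    cbar = float(np.sum(n * ix) / n.sum())
    return {c: idx[c] - cbar for c in classes}


def _severity_variance(config: GeneratorConfig) -> float:
    classes = [c for c in config.class_order if c in config.class_sizes]
    off = _class_offsets(config)
    n = np.array([config.class_sizes[c] for c in classes], dtype=float)
    o = np.array([off[c] for c in classes])
    return float(np.sum(n * o ** 2) / n.sum())


def _within_sd(config: GeneratorConfig, feature: str) -> float:
    """Within-class SD; shrunk for informative features to keep the marginal SD anchored."""
    sd = config.feature_params[feature].sd
    if feature in config.informative_features and config.effect_size > 0:
        return sd / np.sqrt(1.0 + config.effect_size ** 2 * _severity_variance(config))
    return sd


def _class_mean(config: GeneratorConfig, feature: str, class_id: str) -> float:
    base = config.feature_params[feature].mean
    if feature not in config.informative_features:
        return base
    return base + _class_offsets(config)[class_id] * config.effect_size * _within_sd(config, feature)


def _truncnorm_ppf(p: np.ndarray, loc: float, scale: float, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.ppf(p, a, b, loc=loc, scale=scale)


def _exact_count_mask(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with round(fraction·n) True entries at seeded positions.

    Exact counts (instead of independent Bernoulli draws) keep binary and
    zero-inflated columns non-constant within small classes — a constant
    column would make the class unfittable. Both levels are always present.
    """
    k = int(round(fraction * n))
    k = min(max(k, 1), n - 1)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> CohortTable:
    """Draw one seeded synthetic cohort.

    Continuous features are per-class Gaussians clipped to their published
    ranges; BW/BH are drawn jointly (corr 0.4) and BMI derived exactly;
    DI3/DI4 are per-class truncated normals on [0, 550] coupled by a
    Gaussian copula (corr 0.95); gender is coded 1/2 with an exact
    female count of round(female_fraction·n) per class; PLM is zero-inflated
    half-normal with an exact zero count. Identical seeds give identical
    cohorts.
    """
    config = config or GeneratorConfig()
    if overrides:
        from dataclasses import replace
        config = replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = [c for c in config.class_order if c in config.class_sizes]
    P = config.feature_params

    frames: list[np.ndarray] = []
    labels: list[str] = []
    for c in classes:
        n = config.class_sizes[c]
        cols: dict[str, np.ndarray] = {}

        cols["gender"] = 1.0 + _exact_count_mask(rng, n, config.female_fraction)

        for f in ("age", "SBP", "DBP", "ESS", "SOS"):
            x = rng.normal(_class_mean(config, f, c), _within_sd(config, f), n)
            cols[f] = np.clip(x, P[f].lo, P[f].hi)

        # weight/height drawn jointly; BMI is then an exact identity
        rho = config.weight_height_correlation
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        bw = np.clip(_class_mean(config, "BW", c) + _within_sd(config, "BW") * z1,
                     P["BW"].lo, P["BW"].hi)
        bh = np.clip(_class_mean(config, "BH", c) + _within_sd(config, "BH") * z2,
                     P["BH"].lo, P["BH"].hi)
        cols["BW"], cols["BH"] = bw, bh
        cols["BMI"] = bw / (bh / 100.0) ** 2

        rho = config.di_correlation
        z3 = rng.standard_normal(n)
        z4 = rho * z3 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        for f, z in (("DI3", z3), ("DI4", z4)):
            cols[f] = _truncnorm_ppf(stats.norm.cdf(z), _class_mean(config, f, c),
                                     _within_sd(config, f), P[f].lo, P[f].hi)

        nonzero = _exact_count_mask(rng, n, 1.0 - config.plm_zero_fraction)
        plm = np.where(nonzero, np.abs(rng.normal(0.0, 7.6, n)), 0.0)
        # guard: a degenerate half-normal draw of ~0 would re-constant the column
        plm[nonzero] = np.maximum(plm[nonzero], 0.05)
        cols["PLM"] = np.clip(plm, P["PLM"].lo, P["PLM"].hi)

        frames.append(np.column_stack([cols[f] for f in OSA_FEATURES]))
        labels.extend([c] * n)

    values = np.vstack(frames)
    labels_arr = np.array(labels, dtype=object)
    order = rng.permutation(len(labels_arr))
    return CohortTable(list(OSA_FEATURES), values[order], labels_arr[order],
                       config.class_order)


def split_cohort(cohort: CohortTable, train_sizes: dict[str, int] | None = None,
                 seed: int = 0) -> tuple[CohortTable, CohortTable]:
    """Stratified seeded split with exact per-class training counts.

    Defaults reproduce the published 57/29 train/test partition
    (16/23/10/8 training members per severity class). A draw that leaves a
    feature constant within some training class (e.g. an all-male subsample
    of a small class) cannot be fit, so the split is redrawn — still
    deterministically from the seed — until every training class varies in
    every feature.
    """
    train_sizes = train_sizes or dict(DEFAULT_TRAIN_SIZES)
    rng = np.random.default_rng(seed)
    counts = cohort.class_counts()
    for c in cohort.classes_present():
        want = train_sizes.get(c)
        if want is None:
            raise MMTSError(f"no training size given for class '{c}'")
        if want > counts[c]:
            raise MMTSError(f"class '{c}': asked for {want} training members, "
                            f"only {counts[c]} present")
        if want < 2:
            raise MMTSError(f"class '{c}': needs at least 2 training members")
    if sum(counts.values()) == sum(train_sizes[c] for c in cohort.classes_present()):
        raise MMTSError("split leaves an empty test set")

    for _ in range(100):
        train_idx: list[int] = []
        test_idx: list[int] = []
        for c in cohort.classes_present():
            members = np.flatnonzero(cohort.labels == c)
            perm = rng.permutation(members)
            train_idx.extend(perm[:train_sizes[c]].tolist())
            test_idx.extend(perm[train_sizes[c]:].tolist())
        train_idx_a = np.sort(np.array(train_idx))
        # constancy check on the drawn training block, per class
        sub_vals = cohort.values[train_idx_a]
        sub_labs = cohort.labels[train_idx_a]
        degenerate = False
        for c in cohort.classes_present():
            block = sub_vals[sub_labs == c]
            if np.any(block.max(axis=0) == block.min(axis=0)):
                degenerate = True
                break
        if not degenerate:
            test_idx_a = np.sort(np.array(test_idx))
            mk = lambda idx: CohortTable(cohort.feature_names, cohort.values[idx],
                                         cohort.labels[idx], cohort.class_order)
            return mk(train_idx_a), mk(test_idx_a)
    raise MMTSError("could not draw a training split without a constant "
                    "within-class feature; a feature may be constant per class")
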