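import numpy as np
import pytest

from mmts import CohortTable, GeneratorConfig, generate_cohort, split_cohort


def random_members(seed: int, n: int, d: int) -> np.ndarray:
    """Full-rank-with-probability-one Gaussian class members."""
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, d)) @ (np.eye(d) + 0.3 * rng.normal(size=(d, d)))


def gaussian_cohort(seed: int, n_per_class: int, d: int, separation: float,
                    k: int = 2) -> CohortTable:
    """k Gaussian classes with all-feature mean separation, for module tests."""
    rng = np.random.default_rng(seed)
    names = [f"f{j}" for j in range(d)]
    classes = [f"c{i}" for i in range(k)]
    values = np.vstack([rng.normal(i * separation, 1.0, size=(n_per_class, d))
                        for i in range(k)])
    labels = np.repeat(classes, n_per_class)
    return CohortTable(names, values, labels, tuple(classes))


@pytest.fixture
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture
def default_split(default_cohort):
    return split_cohort(default_cohort, seed=7)
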