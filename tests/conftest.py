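import logging

import numpy as np
import pytest

import pairclass as pc

# quiet the expected-path warnings (feature shortfalls, dropped pairs)
logging.getLogger("pairclass").setLevel(logging.ERROR)

#: study-shaped cohort: 5 clusters, 140 samples, smallest (protective) = 14
STUDY_SIZES = {"fc1": 30, "fc2": 30, "fc3": 14, "fc4": 33, "fc5": 33}
STUDY_NOISE_SD = 0.25


@pytest.fixture(scope="session")
def study_cohort():
    """Strong-signal cohort in the study's shape (effect size 4, seed 1)."""
    return pc.generate_cohort(
        140, dict(STUDY_SIZES), n_genes=500, pairs_per_cluster=10,
        effect_size=4.0, noise_sd=STUDY_NOISE_SD, seed=1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 3-cluster cohort for unit tests."""
    return pc.generate_cohort(
        60, {"c1": 10, "c2": 25, "c3": 25}, n_genes=60, pairs_per_cluster=3,
        effect_size=4.0, noise_sd=STUDY_NOISE_SD, seed=11,
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    ranked = pc.rank_pairs(small_cohort.expression, small_cohort.labels)
    return pc.select_features(
        ranked, small_cohort.expression, small_cohort.labels, k_per_cluster=3
    )


def monotone_transform(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random strictly increasing per-sample transform (positive inputs)."""
    n_samples = values.shape[1]
    a = rng.uniform(0.2, 5.0, n_samples)
    g = rng.uniform(0.5, 2.0, n_samples)
    c = rng.uniform(0.0, 3.0, n_samples)
    return a[None, :] * np.power(values, g[None, :]) + c[None, :] * values
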