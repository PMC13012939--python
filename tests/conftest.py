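import dataclasses

import numpy as np
import pytest

from klsnet.atlases import AAL116, DK68, atlas_labels
from klsnet.cohort import (
    DEFAULT_GMV_EFFECT,
    EffectConfig,
    RoiSampleSet,
    generate_cohort,
    generate_roi_samples,
)
from klsnet.network import SimilarityMatrix, build_similarity_matrix


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(4, 4, 4, seed=11)


@pytest.fixture(scope="session")
def small_effect_cfg():
    return dataclasses.replace(DEFAULT_GMV_EFFECT, samples_per_roi_mean=30, seed=7)


@pytest.fixture(scope="session")
def gmv_samples(small_cohort, small_effect_cfg):
    return generate_roi_samples(small_cohort, "GMV", cfg=small_effect_cfg)


@pytest.fixture(scope="session")
def gmv_matrix(gmv_samples):
    return build_similarity_matrix(gmv_samples[0], m=64)


@pytest.fixture(scope="session")
def ct_samples(small_cohort):
    cfg = EffectConfig(samples_per_roi_mean=30, noise_sd=1.0, seed=5)
    return generate_roi_samples(small_cohort, "CT", cfg=cfg)


def random_similarity(n_labels, seed, labels=None):
    """Random valid similarity matrix without running KDE (fast fixture)."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"roi{i:03d}" for i in range(n_labels))
    v = np.zeros((n_labels, n_labels))
    iu = np.triu_indices(n_labels, k=1)
    vals = rng.uniform(0.01, 0.99, size=len(iu[0]))
    v[iu] = vals
    v = v + v.T
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(labels=labels, values=v)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
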