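"""Shared fixtures: small seeded synthetic cohorts and helpers."""

import numpy as np
import pytest

from jackmap import CohortSpec, ThresholdConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """15 subjects, one strong blob, unit noise: quick but non-degenerate."""
    spec = CohortSpec(
        grid_shape=(12, 12, 10),
        n_subjects=15,
        blobs=[((6, 6, 5), 1.5, 1.5)],
        noise_sd=1.0,
        covariates=["age", "handedness"],
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Zero-noise cohort: all subject maps equal the blob template."""
    spec = CohortSpec(
        grid_shape=(10, 10, 8),
        n_subjects=14,
        blobs=[((4, 5, 4), 2.0, 1.2)],
        noise_sd=0.0,
        seed=0,
    )
    return simulate_cohort(spec)


@pytest.fixture
def fdr_config():
    return ThresholdConfig(method="fdr_bh", alpha=0.05)


@pytest.fixture
def fwe_config():
    return ThresholdConfig(method="fwe_bonferroni", alpha=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
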