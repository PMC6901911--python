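"""Shared fixtures: synthetic cohorts at study scale and at unit-test scale.

The full-scale cohort (117 subjects, generator defaults, seed 42) is
generated and featurized once per session; several statistical checks
share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from dilradiomics import plsc
from dilradiomics.pipeline import extract_features, latent_dataset
from dilradiomics.synthcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Generator-default cohort: 117 subjects, strong effect, seed 42."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def study_features(study_cohort):
    return extract_features(study_cohort)


@pytest.fixture(scope="session")
def study_blocks(study_features):
    return plsc.build_blocks(study_features)


@pytest.fixture(scope="session")
def study_model(study_blocks):
    return plsc.fit_plsc(*study_blocks)


@pytest.fixture(scope="session")
def study_selection(study_model):
    return plsc.select_discriminant(study_model)


@pytest.fixture(scope="session")
def study_latents(study_selection):
    return latent_dataset(study_selection)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects on small volumes for structural / integration tests."""
    cfg = CohortConfig(n_subjects=12, volume_shape=(10, 48, 48),
                       dil_radius=7, n_group_b=4, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, subjects = small_cohort
    return extract_features(subjects)


@pytest.fixture(scope="session")
def small_fit(small_features):
    bx, by = plsc.build_blocks(small_features)
    model = plsc.fit_plsc(bx, by)
    sel = plsc.select_discriminant(model)
    return model, sel


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
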