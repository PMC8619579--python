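"""Shared fixtures: a scaled-down synthetic study and trained VAE models.

The study keeps the default condition parameters (gains, plane angles,
ellipse axes, noise) but uses 60 s per condition instead of 3 min so the
whole suite stays fast; tests that depend on per-condition structure use
these session fixtures rather than regenerating data.
"""
from __future__ import annotations

import numpy as np
import pytest

from aculatent import SyntheticConfig, generate_study
from aculatent.pipeline import (
    PipelineConfig, geometry_tables, preprocess_study, train_subject_models,
)


@pytest.fixture(scope="session")
def study_cfg() -> SyntheticConfig:
    return SyntheticConfig(n_subjects=4, duration_s=60.0)


@pytest.fixture(scope="session")
def pipeline_cfg(study_cfg) -> PipelineConfig:
    return PipelineConfig(synthetic=study_cfg)


@pytest.fixture(scope="session")
def study(study_cfg):
    return generate_study(study_cfg)


@pytest.fixture(scope="session")
def preprocessed_study(study, pipeline_cfg):
    return preprocess_study(study, pipeline_cfg)


@pytest.fixture(scope="session")
def subject_models(preprocessed_study, pipeline_cfg):
    models, histories = train_subject_models(preprocessed_study, pipeline_cfg)
    return models, histories


@pytest.fixture(scope="session")
def geometry_results(preprocessed_study, subject_models, pipeline_cfg):
    models, _ = subject_models
    planes, features = geometry_tables(preprocessed_study, models, pipeline_cfg)
    return planes, features
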