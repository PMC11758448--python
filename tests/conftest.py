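"""Shared fixtures: phantom cohorts and (expensive) trained models.

The desk-scale end-to-end fit and the single-pair memorization run are
session-scoped so every test that needs a trained network shares one run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from sect2mdi import (MaterialDecompositionGAN, ModelConfig, PhantomConfig,
                      TrainConfig, simulate_case, simulate_cohort)


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def clean_config(phantom_config) -> PhantomConfig:
    """Noiseless, blur-free variant: the forward model holds exactly."""
    return replace(phantom_config, noise_sd=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def one_case(phantom_config):
    return simulate_case(phantom_config, seed=5)


# small architecture for fast structural tests (16^2 inputs)
TINY_MODEL = ModelConfig(patch_size=2, embed_dim=8, head_counts=(1, 1, 2, 2),
                         window_size=2)


@pytest.fixture(scope="session")
def memorization_run(phantom_config):
    """Single-pair overfitting run (L1 only), shared across tests."""
    case = simulate_case(phantom_config, seed=5, force_label="CS")
    model = MaterialDecompositionGAN(
        [case], ModelConfig(),
        TrainConfig(iterations=400, batch_size=1, adversarial=False,
                    augment=False, seed=0))
    return case, model.fit()


@pytest.fixture(scope="session")
def desk_scale_fit(phantom_config):
    """Full desk-scale study: 200 training phantoms, 40 held-out, 800 iterations.

    This is the package's scaled-down analogue of the clinical training run;
    the cohort sizes and seeds are fixed study conditions.
    """
    train_cases = simulate_cohort(phantom_config, 200, seed=1001)
    val_cases = simulate_cohort(phantom_config, 40, seed=2002)
    model = MaterialDecompositionGAN(
        train_cases, ModelConfig(), TrainConfig(iterations=800, seed=7))
    return train_cases, val_cases, model.fit()
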