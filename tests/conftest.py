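"""Shared fixtures: scaled-down synthetic cohorts and preprocessing helpers.

The fixtures shrink the study's structure (fewer masks/sequences/features,
smaller cohort) so every stage runs in seconds while keeping the properties
the pipeline depends on: low-rank blocks, class-dependent separation,
block missingness, class imbalance.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from radlatent.cohort import CohortSpec, generate_cohort
from radlatent.latent import TrainConfig
from radlatent.models import MLPParams
from radlatent.preprocessing import (ImputationStrategy, apply_standardizer,
                                     fit_standardizer, impute,
                                     split_matrix_by_mask)


def make_small_spec(effect: float = 4.0, seed: int = 11,
                    counts: dict | None = None) -> CohortSpec:
    """A two-mask, two-sequence miniature of the study cohort."""
    return CohortSpec(
        class_counts=counts or {"GBM": 40, "LYM": 25, "MET": 45},
        masks=("whole", "necrotic"),
        sequences=("T1W", "ADC"),
        features_per_combination=12,
        intrinsic_rank=4,
        class_effect={"GBM": effect, "LYM": 0.4 * effect, "MET": effect},
        missing_rates={("necrotic", "LYM"): 0.3},
        noise_sd=0.3,
        seed=seed,
    )


def preprocess_blocks(cohort, strategy=ImputationStrategy("mean")):
    """Standardize + impute a full cohort, split into per-mask blocks."""
    params = fit_standardizer(cohort.features)
    X = impute(apply_standardizer(cohort.features, params), strategy)
    return {b.mask: b.values
            for b in split_matrix_by_mask(X, cohort.column_meta, cohort.masks)}


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(make_small_spec())


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    return preprocess_blocks(small_cohort)


@pytest.fixture(scope="session")
def fast_ae_cfg():
    return TrainConfig(max_epochs=60, patience=8, seed=0)


@pytest.fixture(scope="session")
def fast_mlp_params():
    return MLPParams(batch_size=32, hidden_nodes=50, hidden_layers=1,
                     learning_rate=1e-3, solver="adam", seed=0)


@pytest.fixture(scope="session")
def rank3_block():
    """A standardized, complete low-rank block for autoencoder tests."""
    rng = np.random.default_rng(42)
    n, d_latent, D = 120, 3, 24
    W = rng.normal(size=(D, d_latent)) / np.sqrt(d_latent)
    X = rng.standard_normal((n, d_latent)) @ W.T
    X = X + 0.15 * rng.standard_normal((n, D))
    params = fit_standardizer(X)
    return apply_standardizer(X, params)
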