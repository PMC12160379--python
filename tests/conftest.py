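"""Shared fixtures: one small synthetic cohort and fitted models reused
across test modules (fits are the expensive resource; session scope keeps the
suite fast without weakening any check)."""

from __future__ import annotations

import numpy as np
import pytest

from gaitpower import (
    GeneratorConfig,
    ModelSpec,
    build_design,
    fit,
    prepare_waveforms,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 participants, all joints, default noise/effects."""
    cfg = GeneratorConfig(n_participants=60, seed=42)
    covs, waves, truth = simulate_dataset(cfg)
    return cfg, covs, waves, truth


@pytest.fixture(scope="session")
def ankle_design_small(small_dataset):
    _, covs, waves, _ = small_dataset
    ready = prepare_waveforms(waves)
    spec = ModelSpec.for_joint("ankle", "compact", maxiter=60)
    return build_design(ready, covs, spec)


@pytest.fixture(scope="session")
def ankle_fit_small(ankle_design_small):
    return fit(ankle_design_small)


@pytest.fixture(scope="session")
def noiseless_fit():
    """Noise-free, study-free cohort and its fit: used for exact-structure
    checks (monotone speed response, trajectory recovery)."""
    cfg = GeneratorConfig(n_participants=150, seed=7, noise_sd=0.0, study_sd=0.0)
    covs, waves, truth = simulate_dataset(cfg, joints=("ankle",))
    ready = prepare_waveforms(waves)
    spec = ModelSpec.for_joint("ankle", "compact", maxiter=60)
    return covs, truth, fit(build_design(ready, covs, spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
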