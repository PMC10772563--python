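"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from ecgdynrisk import experiments, synthetic

warnings.filterwarnings("ignore", message=".*Early stopping criterion.*")

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pool_vae():
    """Encoder trained once on the 5,000-template synthetic pool.

    Shared across reconstruction, experiment and interpretation tests; the
    training conditions (pool size, 200-epoch budget with early stopping,
    hidden sizes) are the package defaults for template-sized inputs.
    """
    model, holdout = experiments.train_pool_vae(5000, seed=0, epochs=200)
    return model, holdout


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient cohort at the default study conditions."""
    return synthetic.generate_cohort(
        synthetic.CohortConfig(n_patients=80), seed=7
    )


@pytest.fixture(scope="session")
def clean_recording():
    """One noiseless 10-s recording at 250 Hz with known morphology."""
    params = synthetic.default_morphology()
    rec = synthetic.synthesize_ecg(params, duration=10.0, fs=250)
    return params, rec
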