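"""Shared fixtures.

The recognizer trained here is session-scoped because CPU training is the
dominant cost of the suite; every test that needs a competent model shares
one instance trained on seeded synthetic soundscapes.
"""

from __future__ import annotations

import numpy as np
import pytest

from broilervox.recognizer import (
    RecognizerConfig,
    TrainingConfig,
    build_model,
    synthesize_training_set,
    train,
)

#: Small architecture for fast unit tests of the training machinery
#: (parameter-count contract intentionally not enforced).
TINY_CONFIG = dict(
    channels=((8, 8), (12,), (16,), (24, 24)),
    strides=((2, 2), (2, 2), (2, 2), (3, 2)),
    enforce_param_contract=False,
)


def tiny_config(seed: int = 0, **training) -> RecognizerConfig:
    tc = TrainingConfig(**{"epochs": 4, "batch_size": 32, **training})
    return RecognizerConfig(seed=seed, training=tc, **TINY_CONFIG)


@pytest.fixture(scope="session")
def trained_model():
    """Default-architecture recognizer trained on 20 minutes of seeded
    synthetic soundscapes at 20 dB SNR (>= 200 labeled steps per class)."""
    data = synthesize_training_set(n_minutes=20, snr_db=20.0, seed=11)
    counts = np.bincount(data.labels.ravel(), minlength=6)
    assert counts.min() >= 200, counts
    cfg = RecognizerConfig(
        seed=7, training=TrainingConfig(epochs=21, learning_rate=1.2e-3, batch_size=16)
    )
    model = build_model(cfg)
    model, history = train(model, data, cfg)
    return model


@pytest.fixture(scope="session")
def heldout_data():
    """Held-out labeled clips from seeds disjoint from training."""
    return synthesize_training_set(n_minutes=4, snr_db=20.0, seed=9090)
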