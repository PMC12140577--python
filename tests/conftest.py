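"""Shared fixtures: small synthetic datasets and a cached trained VAE."""

import numpy as np
import pytest

from latentgec.io import BoldTimeSeries, PatternSet, build_pattern_set
from latentgec.vae import TrainConfig, VaeSpec, train_vae


@pytest.fixture(scope="session")
def rank3_patterns() -> PatternSet:
    """Patterns lying exactly in a 3-dim linear subspace of N=20."""
    rng = np.random.default_rng(42)
    W = rng.standard_normal((20, 3))
    series = []
    for s in range(8):
        z = rng.standard_normal((150, 3))
        series.append(BoldTimeSeries(
            data=z @ W.T, tr_seconds=0.72, subject_id=f"s{s}",
        ))
    return build_pattern_set(series, train_frac=0.875, normalize=True, seed=0)


@pytest.fixture(scope="session")
def rank3_vae(rank3_patterns):
    """VAE with M=3 trained on the rank-3 patterns (shared across tests)."""
    spec = VaeSpec(input_dim=20, latent_dim=3)
    cfg = TrainConfig(batch_size=128, epochs=1200, seed=0)
    return train_vae(rank3_patterns, spec, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
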