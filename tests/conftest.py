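"""Shared fixtures.

The multi-seed benchmark fixture is expensive (it trains five VAEs) and is
therefore session-scoped and shared by every test that needs a trained
full-size model; the tiny worked-fixture model trains in well under a
second and backs the cheap functional tests.
"""

import numpy as np
import pytest

from modvae import pipeline, synthetic_data
from modvae.data_io import SplitSpec, log_normalize, split_samples
from modvae.vae_core import ArchitectureSpec, TrainingSchedule, build_vae, train

BENCH_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def bench5():
    """Full synthetic pipeline results for the five default seeds."""
    return [pipeline.run_synthetic_benchmark(seed=s) for s in BENCH_SEEDS]


@pytest.fixture(scope="session")
def fixture_bundle():
    return synthetic_data.worked_fixture()


@pytest.fixture(scope="session")
def tiny_model(fixture_bundle):
    """A small VAE trained on the 30-gene worked fixture."""
    norm = log_normalize(fixture_bundle["expression"])
    tr, va, te = split_samples(norm, SplitSpec(seed=0))
    spec = ArchitectureSpec(input_dim=30, encoder_hidden=16, latent_dim=6,
                            decoder_hidden=16)
    model = build_vae(spec, seed=0, gene_ids=norm.gene_ids)
    schedule = TrainingSchedule(stages=[(150, 100.0), (150, 10.0)],
                                batch_size=8, seed=0)
    train(model, tr, va, schedule)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
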