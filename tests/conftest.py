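"""Shared fixtures.

The expensive fixtures (simulated datasets, trained models) are
session-scoped so that property tests and the acceptance suite share one
training run instead of repeating it.
"""

from __future__ import annotations

import numpy as np
import pytest

import legnet as lg
from legnet.arch import LegNetConfig


def micro_config(n_blocks: int = 2) -> LegNetConfig:
    """Very small architecture for fast property tests."""
    return LegNetConfig(
        stem_channels=16,
        block_channels=(8,) * n_blocks,
        conv_mode="grouped",
        group_size=4,
        se_variant="efficientnetv2",
        se_reduction=4,
        expansion_policy="fixed_ratio",
        expansion_ratio=1.0,
    )


@pytest.fixture(scope="session")
def sim_dataset_small():
    """6k-row simulated assay for quick training checks."""
    cfg = lg.SimulatorConfig(n_sequences=6_000, n_test=800, seed=101)
    return cfg, lg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_dataset_full():
    """The 50k-row dataset used by the parameter-recovery acceptance check."""
    cfg = lg.SimulatorConfig(n_sequences=50_000, n_test=2_000, seed=11)
    return cfg, lg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_tiny_predictor(sim_dataset_full):
    """Tiny predictor trained 5 epochs on the 50k simulated rows."""
    _, ds = sim_dataset_full
    tc = lg.TrainConfig(batch_size=256, epochs=5, seed=7, frame_length=80)
    model, log = lg.train_predictor(ds.train, tc, lg.tiny_config())
    return model, log, ds


@pytest.fixture(scope="session")
def trained_micro_predictor(sim_dataset_small):
    """Micro predictor for cheap behavioural tests (not accuracy claims)."""
    _, ds = sim_dataset_small
    tc = lg.TrainConfig(batch_size=128, epochs=2, seed=3, frame_length=80)
    model, log = lg.train_predictor(ds.train, tc, micro_config())
    return model, log, ds


@pytest.fixture(scope="session")
def trained_generator(sim_dataset_full):
    """Denoiser trained on the simulated data for design tests.

    Keeps the reference batch size (1024) and scales down batches/epoch:
    the expression-conditioning gradient is weak and low-variance, and
    small batches drown it (see docs/methods.md).
    """
    _, ds = sim_dataset_full
    dcfg = lg.DiffusionConfig(seed=5)
    gcfg = lg.GeneratorTrainConfig(
        epochs=4, batch_size=1024, batches_per_epoch=50, seed=5
    )
    gen, log = lg.train_generator(ds.train, dcfg, gcfg, lg.tiny_config())
    return gen, log, dcfg, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
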