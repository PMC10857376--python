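"""Shared fixtures: scaled-down synthetic benchmarks and model configs.

The session-scoped "full" benchmark uses the generator's default study
conditions (data-rich source, small target); the "small" one shrinks every
dimension for fast unit tests while keeping the same structure.
"""

from __future__ import annotations

import numpy as np
import pytest

from yieldtransfer.gp_head import GPConfig
from yieldtransfer.model import ModelConfig
from yieldtransfer.pipeline import (
    SourceModelCache,
    evaluate_transfer_config,
    prepare_benchmark,
)
from yieldtransfer.evaluation import standard_configs
from yieldtransfer.synthdata import SynthConfig


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_source_counties=12,
        n_target_counties=8,
        seasons_source=(2010, 2014),
        seasons_target=(2012, 2014),
        pixels_per_county=(150, 200),
        cleansing_min_pixels=120,
        below_min_fraction=0.25,
        residual_sd=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bench(small_config):
    return prepare_benchmark(small_config, edge_sample_records=10)


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig(
        channels_per_layer=(4, 4, 8, 8, 16, 16),
        dense_dim=16,
        max_epochs=30,
        early_stopping_patience=5,
        batch_size=32,
        seed=0,
    )


@pytest.fixture(scope="session")
def full_bench():
    """Default study conditions: ~1550 source / ~190 target county-seasons."""
    return prepare_benchmark(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def transfer_runs(full_bench):
    """Four seeded replicates of the no-transfer baseline and the full
    transfer recipe (source init + freeze 4 + L2-SP) on the last season."""
    mc = ModelConfig()
    gc = GPConfig()
    cache = SourceModelCache(full_bench, mc)
    configs = standard_configs()
    season = int(full_bench.target.seasons.max())
    out: dict[str, list[dict]] = {"no_transfer": [], "freeze_l2sp": []}
    for label in out:
        for seed in range(4):
            out[label].append(
                evaluate_transfer_config(
                    full_bench, configs[label], mc, gc, season, seed, cache
                )
            )
    return out
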