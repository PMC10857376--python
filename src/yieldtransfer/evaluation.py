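"""Metrics, the rolling-origin season protocol, and the experiment matrix.

Models are scored by RMSE (bu/ac) and the coefficient of determination

    RMSE(ŷ, y) = sqrt(mean((ŷ − y)²)),
    R²(ŷ, y)   = 1 − Σ(y − ŷ)² / Σ(y − ȳ)².

Seasonal forecasting forbids temporal leakage: for each test season only
strictly earlier seasons may be trained on, in both domains (the source
model feeding a transfer run is cut off at the same season).  Every
configuration is evaluated over several independently seeded runs and the
per-run scores averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import YieldRecord
from .gp_head import GPConfig
from .model import ModelConfig
from .pipeline import Benchmark, SourceModelCache, evaluate_transfer_config
from .transfer import TransferConfig

__all__ = [
    "rmse",
    "r2",
    "rolling_origin_splits",
    "ExperimentResult",
    "standard_configs",
    "run_matrix",
    "results_table",
]


def rmse(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def r2(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination (can be negative; undefined for constant y)."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 is undefined for a constant ground truth")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def rolling_origin_splits(
    records: Sequence[YieldRecord],
    first_test_season: int,
    last_test_season: int,
) -> list[tuple[list[YieldRecord], list[YieldRecord]]]:
    """One (train, test) split per test season; train = strictly earlier seasons.

    The rule is applied per record, so mixed-domain record lists are split
    independently per domain by construction.
    """
    if last_test_season < first_test_season:
        raise ValueError("last_test_season must be >= first_test_season")
    splits = []
    for season in range(first_test_season, last_test_season + 1):
        train = [r for r in records if r.season_year < season]
        test = [r for r in records if r.season_year == season]
        if season == first_test_season and not train:
            raise ValueError(
                f"no training seasons before the earliest test season {season}"
            )
        splits.append((train, test))
    return splits


@dataclass
class ExperimentResult:
    """Per-season, per-run scores of one configuration, plus aggregates."""

    label: str
    per_run: pd.DataFrame = field(default_factory=pd.DataFrame)

    def _mean(self, col: str) -> float:
        return float(self.per_run[col].mean())

    @property
    def rmse(self) -> float:
        return self._mean("rmse")

    @property
    def r2(self) -> float:
        return self._mean("r2")

    @property
    def rmse_gp(self) -> float:
        return self._mean("rmse_gp")

    @property
    def r2_gp(self) -> float:
        return self._mean("r2_gp")


def standard_configs() -> dict[str, TransferConfig | None]:
    """The benchmark's transfer-strategy ladder.

    From no transfer at all up to the full method: source initialization,
    four frozen layers, L2-SP (α=0.23, β=0.77) and/or BSS (η=0.07, k=1).
    """
    return {
        "no_transfer": None,
        "freeze": TransferConfig(
            n_frozen_layers=4, source_init=True, penalty="none", eta=0.0
        ),
        "freeze_l2sp": TransferConfig(
            n_frozen_layers=4, source_init=True, penalty="l2sp", eta=0.0
        ),
        "freeze_l2_bss": TransferConfig(
            n_frozen_layers=4, source_init=True, penalty="l2", alpha=0.23,
            eta=0.07, k=1,
        ),
        "freeze_l2sp_bss": TransferConfig(
            n_frozen_layers=4, source_init=True, penalty="l2sp", eta=0.07, k=1
        ),
    }


def run_matrix(
    configs: dict[str, TransferConfig | None],
    data: Benchmark,
    n_runs: int = 4,
    seeds: Sequence[int] | None = None,
    test_seasons: Sequence[int] | None = None,
    model_config: ModelConfig | None = None,
    gp_config: GPConfig | None = None,
    source_cache: SourceModelCache | None = None,
) -> dict[str, ExperimentResult]:
    """Evaluate every configuration, with and without GP, over multiple runs.

    Each (run, test season) trains one target model and scores its raw and
    GP-corrected predictions; source models are shared across configurations
    for a given (season, seed).  Deterministic given the seed list.
    """
    seeds = list(seeds) if seeds is not None else list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("seeds must have n_runs entries")
    mc = model_config or ModelConfig()
    gc = gp_config or GPConfig()
    if test_seasons is None:
        uniq = np.unique(data.target.seasons)
        test_seasons = uniq[-2:] if uniq.size > 2 else uniq[-1:]

    if source_cache is None:
        source_cache = SourceModelCache(data, mc)
    results: dict[str, ExperimentResult] = {}
    for label, tc in configs.items():
        rows = []
        for seed in seeds:
            for season in test_seasons:
                out = evaluate_transfer_config(
                    data, tc, mc, gc, int(season), int(seed), source_cache
                )
                rows.append(
                    {
                        "config": label,
                        "seed": seed,
                        "season": int(season),
                        "n_test": out["n_test"],
                        "rmse": rmse(out["y_hat"], out["y_true"]),
                        "r2": r2(out["y_hat"], out["y_true"]),
                        "rmse_gp": rmse(out["y_hat_gp"], out["y_true"]),
                        "r2_gp": r2(out["y_hat_gp"], out["y_true"]),
                    }
                )
        results[label] = ExperimentResult(label=label, per_run=pd.DataFrame(rows))
    return results


def results_table(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """Aggregate grid: one row per configuration, GP off/on side by side."""
    return pd.DataFrame(
        {
            "RMSE": {k: v.rmse for k, v in results.items()},
            "R2": {k: v.r2 for k, v in results.items()},
            "RMSE+GP": {k: v.rmse_gp for k, v in results.items()},
            "R2+GP": {k: v.r2_gp for k, v in results.items()},
        }
    )
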