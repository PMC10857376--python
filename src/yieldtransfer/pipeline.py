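"""End-to-end plumbing: generator → cleansing → histograms → models → GP.

This module turns a :class:`~yieldtransfer.synthdata.SynthConfig` into
rectangular training arrays (streaming the pixel cubes so the full source
domain never sits in memory), trains source and target models under a given
transfer strategy, and applies the GP correction — one county-season test
split at a time, honouring the rolling-origin rule in both domains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .features import (
    DEFAULT_N_BINS,
    align_period,
    clean_records,
    compute_bin_edges,
    histogramize,
)
from .gp_head import GPConfig, STIndex, gp_fit_predict
from .model import (
    ModelConfig,
    YieldCNN,
    build_model,
    penultimate_features,
    predict,
    train,
)
from .synthdata import SynthConfig, generate_domains, iter_series
from .transfer import TransferConfig, build_loss_terms, freeze_layers, init_from_source

__all__ = [
    "DomainData",
    "Benchmark",
    "prepare_benchmark",
    "train_source_model",
    "evaluate_transfer_config",
    "SourceModelCache",
]


@dataclass
class DomainData:
    """Model-ready arrays of one domain."""

    domain: str
    X: np.ndarray            # [n, 9, T, bins] histogram tensors
    y: np.ndarray            # [n] yields, bu/ac
    seasons: np.ndarray      # [n] season years
    county_ids: list[str]
    st_index: list[STIndex]
    signal: np.ndarray       # [n] latent noise-free yields (oracle)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class Benchmark:
    source: DomainData
    target: DomainData
    edges: np.ndarray        # [9, n_bins+1] shared per-band bin edges
    config: SynthConfig
    short_period: bool


def prepare_benchmark(
    config: SynthConfig,
    short_period: bool = False,
    n_bins: int = DEFAULT_N_BINS,
    edge_sample_records: int = 48,
    edge_pixel_stride: int = 7,
) -> Benchmark:
    """Generate, cleanse, align and histogramize both domains.

    Bin edges are per-band quantiles estimated from a pixel sample pooled
    over the first ``edge_sample_records`` cleansed source county-seasons,
    then frozen and shared by both domains (transfer needs one feature
    space).  ``short_period`` keeps only the first 14 composites.
    """
    src_bundle, tgt_bundle = generate_domains(config, with_series=False)

    edges: np.ndarray | None = None
    buffer: list = []
    out: dict[str, DomainData] = {}
    for bundle in (src_bundle, tgt_bundle):
        kept = clean_records(
            bundle.records, bundle.mask_counts, config.cleansing_min_pixels
        )
        kept_keys = {(r.county_id, r.season_year) for r in kept}
        keep_mask = np.array(
            [(r.county_id, r.season_year) in kept_keys for r in bundle.records]
        )

        tensors: list[np.ndarray] = []
        for series, keep in zip(iter_series(config, bundle.domain), keep_mask):
            if not keep:
                continue
            series = align_period(series, bundle.calendar, short_period)
            if bundle.domain == "source" and edges is None:
                buffer.append(series)
                if len(buffer) == edge_sample_records:
                    edges = _edges_from_sample(buffer, n_bins, edge_pixel_stride)
                    tensors.extend(
                        histogramize(s, edges).data.astype(np.float32) for s in buffer
                    )
                    buffer = []
                continue
            tensors.append(histogramize(series, edges).data.astype(np.float32))
        if buffer:  # fewer kept source records than the sample size
            edges = _edges_from_sample(buffer, n_bins, edge_pixel_stride)
            tensors = [
                histogramize(s, edges).data.astype(np.float32) for s in buffer
            ] + tensors
            buffer = []

        idx = np.flatnonzero(keep_mask)
        out[bundle.domain] = DomainData(
            domain=bundle.domain,
            X=np.stack(tensors),
            y=np.array([bundle.records[i].yield_bu_ac for i in idx]),
            seasons=np.array([bundle.records[i].season_year for i in idx]),
            county_ids=[bundle.records[i].county_id for i in idx],
            st_index=[bundle.st_index[i] for i in idx],
            signal=bundle.signal[idx],
        )
    return Benchmark(
        source=out["source"],
        target=out["target"],
        edges=np.asarray(edges),
        config=config,
        short_period=short_period,
    )


def _edges_from_sample(series_buffer, n_bins: int, stride: int) -> np.ndarray:
    n_bands = series_buffer[0].values.shape[0]
    edges = np.empty((n_bands, n_bins + 1))
    for b in range(n_bands):
        pooled = np.concatenate(
            [s.values[b].ravel()[::stride] for s in series_buffer]
        )
        edges[b] = compute_bin_edges(pooled, n_bins, band=b)
    return edges


def train_source_model(
    bench: Benchmark,
    model_config: ModelConfig,
    cutoff_season: int,
    seed: int,
) -> YieldCNN:
    """Train the source-domain CNN on seasons strictly before ``cutoff_season``.

    The rolling-origin rule applies to the source domain too: the source
    model feeding a given target test season may only see earlier seasons.
    """
    src = bench.source
    tr = src.seasons < cutoff_season
    if not tr.any():
        raise ValueError(f"no source seasons before {cutoff_season}")
    cfg = replace(model_config, seed=seed)
    model, _ = build_model(cfg, input_shape=src.X.shape[1:])
    train(model, (src.X[tr], src.y[tr]), (), cfg, seasons=src.seasons[tr])
    return model


class SourceModelCache:
    """Memoizes source models per (cutoff season, seed) across configs."""

    def __init__(self, bench: Benchmark, model_config: ModelConfig):
        self.bench = bench
        self.model_config = model_config
        self._cache: dict[tuple[int, int], YieldCNN] = {}

    def get(self, cutoff_season: int, seed: int) -> YieldCNN:
        key = (cutoff_season, seed)
        if key not in self._cache:
            self._cache[key] = train_source_model(
                self.bench, self.model_config, cutoff_season, seed
            )
        return self._cache[key]


def evaluate_transfer_config(
    bench: Benchmark,
    transfer_config: TransferConfig | None,
    model_config: ModelConfig,
    gp_config: GPConfig,
    test_season: int,
    seed: int,
    source_cache: SourceModelCache | None = None,
) -> dict:
    """Train one target model and predict one test season, with and without GP.

    ``transfer_config=None`` (or ``source_init=False`` with nothing frozen
    and no penalties) is the no-transfer baseline.  Returns predictions and
    ground truth; metric aggregation is the caller's concern.
    """
    tgt = bench.target
    tr = tgt.seasons < test_season
    te = tgt.seasons == test_season
    if not tr.any():
        raise ValueError(f"no target training seasons before {test_season}")
    if not te.any():
        raise ValueError(f"no target records in test season {test_season}")

    cfg = replace(model_config, seed=seed)
    model, _ = build_model(cfg, input_shape=tgt.X.shape[1:])

    terms: Sequence = ()
    tc = transfer_config
    needs_source = tc is not None and (
        tc.source_init or tc.n_frozen_layers > 0 or tc.penalty == "l2sp"
    )
    if needs_source:
        if source_cache is None:
            source_cache = SourceModelCache(bench, model_config)
        src_model = source_cache.get(test_season, seed)
        src_ws = src_model.get_weights()
        if tc.source_init:
            model.set_weights(init_from_source(model.get_weights(), src_ws))
        freeze_layers(model, tc.n_frozen_layers)
        terms = build_loss_terms(tc, src_ws)
    elif tc is not None:
        terms = build_loss_terms(tc, None)

    train(model, (tgt.X[tr], tgt.y[tr]), terms, cfg, seasons=tgt.seasons[tr])

    y_hat = predict(model, tgt.X[te])
    H_tr = penultimate_features(model, tgt.X[tr])
    H_te = penultimate_features(model, tgt.X[te])
    idx_tr = [tgt.st_index[i] for i in np.flatnonzero(tr)]
    idx_te = [tgt.st_index[i] for i in np.flatnonzero(te)]
    y_hat_gp = gp_fit_predict(
        H_tr,
        tgt.y[tr],
        idx_tr,
        H_te,
        idx_te,
        model.dense2.W[:, 0],
        gp_config,
        b_last=float(model.dense2.b[0]),
    )
    return {
        "y_true": tgt.y[te],
        "y_hat": y_hat,
        "y_hat_gp": y_hat_gp,
        "test_season": test_season,
        "seed": seed,
        "n_test": int(te.sum()),
        "model": model,
    }
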